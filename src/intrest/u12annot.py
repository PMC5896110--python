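"""Classify reference introns as U12-type (minor spliceosome) or U2-type.

Minor-spliceosome introns carry highly conserved, divergent 5' splice-site and
branch-point motifs; scoring both against position weight matrices separates
them from the major (U2-type) class.  An intron is called U12 when the
relative log-odds score of its donor site and of the best branch-point window
both reach their thresholds; otherwise it is called U2 if it has canonical
GT..AG or AT..AC termini, and left unannotated if not.

Relative scores are scale-free: (score - min attainable) / (max - min), so a
threshold of 0.8 means "within the top 20% of the score range of this PWM".
The packaged default matrices encode the published U12 donor (GTATCCTT) and
branch-point (TTCCTTAAC, branch adenosine at position 8) consensus
frequencies and a U2 donor (GTAAGT) matrix scored for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .refprep import ReferenceRow

__all__ = [
    "PWM",
    "U12Params",
    "IntronClassification",
    "load_pwm",
    "default_pwms",
    "score_pwm",
    "relative_score",
    "classify_introns",
    "annotate_reference",
    "write_classification_tsv",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

UNIFORM_BACKGROUND: Mapping[str, float] = {b: 0.25 for b in _BASES}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PWM:
    """Position probability matrix over ACGT.

    ``offset_to_anchor`` is the column index of the biologically anchored
    base: the first intron base for donor matrices, the branch adenosine for
    branch-point matrices.
    """

    name: str
    offset_to_anchor: int
    probabilities: np.ndarray  # shape (4, n_cols), rows A,C,G,T

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.ndim != 2 or p.shape[0] != 4:
            raise ValueError("PWM needs a 4 x n probability matrix (rows A,C,G,T)")
        if (p < 0).any():
            raise ValueError("PWM probabilities must be non-negative")
        if not np.allclose(p.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError(f"PWM {self.name}: columns must sum to 1")
        self.probabilities = p

    @property
    def n_cols(self) -> int:
        return self.probabilities.shape[1]

    def floored(self, floor: float = 1e-3) -> "PWM":
        """Apply a pseudo-probability floor and renormalize so log-odds are finite."""
        p = np.maximum(self.probabilities, floor)
        p = p / p.sum(axis=0, keepdims=True)
        return PWM(self.name, self.offset_to_anchor, p)


def load_pwm(path: str | Path, name: str | None = None) -> PWM:
    """Read a PWM TSV: ``#anchor=<int>`` metadata line, a position header row,
    then four rows labeled A, C, G, T."""
    anchor = 0
    rows: dict[str, list[float]] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#anchor="):
                    anchor = int(line.split("=", 1)[1])
                continue
            fields = line.split("\t")
            if fields[0] in _BASE_INDEX:
                rows[fields[0]] = [float(x) for x in fields[1:]]
    if set(rows) != set(_BASES):
        raise ValueError(f"{path}: PWM must have rows A,C,G,T (got {sorted(rows)})")
    mat = np.array([rows[b] for b in _BASES])
    return PWM(name or Path(path).stem, anchor, mat).floored()


def default_pwms() -> dict[str, PWM]:
    """The packaged U12 donor, U12 branch-point, and U2 donor matrices."""
    pkg = resources.files("intrest") / "data" / "pwms"
    return {
        "u12_donor": load_pwm(str(pkg / "u12_donor.tsv"), "u12_donor"),
        "u12_branchpoint": load_pwm(str(pkg / "u12_branchpoint.tsv"), "u12_branchpoint"),
        "u2_donor": load_pwm(str(pkg / "u2_donor.tsv"), "u2_donor"),
    }


def consensus(pwm: PWM) -> str:
    """Highest-probability base per column."""
    return "".join(_BASES[i] for i in np.argmax(pwm.probabilities, axis=0))


def score_pwm(
    pwm: PWM,
    sequence: str,
    background: Mapping[str, float] = UNIFORM_BACKGROUND,
) -> float:
    """Log2-odds score of ``sequence`` against ``pwm``; N contributes 0."""
    if len(sequence) != pwm.n_cols:
        raise ValueError(
            f"sequence length {len(sequence)} != PWM width {pwm.n_cols}"
        )
    score = 0.0
    for j, base in enumerate(sequence.upper()):
        if base == "N":
            continue
        try:
            i = _BASE_INDEX[base]
        except KeyError:
            raise ValueError(f"invalid base {base!r} in sequence") from None
        score += np.log2(pwm.probabilities[i, j] / background[base])
    return float(score)


def _score_bounds(pwm: PWM, background: Mapping[str, float]) -> tuple[float, float]:
    bg = np.array([background[b] for b in _BASES])[:, None]
    lo = np.log2(pwm.probabilities / bg)
    return float(lo.min(axis=0).sum()), float(lo.max(axis=0).sum())


def relative_score(
    pwm: PWM, sequence: str, background: Mapping[str, float] = UNIFORM_BACKGROUND
) -> float:
    """Score rescaled to [0, 1] by the PWM's attainable min/max."""
    lo, hi = _score_bounds(pwm, background)
    return (score_pwm(pwm, sequence, background) - lo) / (hi - lo)


@dataclass
class U12Params:
    donor_threshold: float = 0.8     # relative-score cutoff for the U12 donor
    bp_threshold: float = 0.8        # relative-score cutoff for the branch point
    bp_search_start: int = -40       # window start range, nt relative to intron 3' end
    bp_search_end: int = -5
    background: Mapping[str, float] = field(default_factory=lambda: dict(UNIFORM_BACKGROUND))


@dataclass
class IntronClassification:
    intron_key: tuple[str, int]  # (gene_id, ordinal)
    donor_score_u12: float
    bp_score_u12: float
    donor_score_u2: float
    donor_rel_u12: float
    bp_rel_u12: float
    donor_rel_u2: float
    best_bp_offset: int | None   # window start relative to intron 3' end
    assigned_class: str          # U12 | U2 | unannotated
    terminal_dinucleotides: tuple[str, str]
    too_short: bool = False


def _intron_seq(genome, chrom: str, start: int, end: int, strand: str) -> str:
    seq = str(genome[chrom][start:end]).upper()
    return reverse_complement(seq) if strand == "-" else seq


def classify_introns(
    reference: Sequence[ReferenceRow],
    genome,
    donor_pwm_u12: PWM | None = None,
    bp_pwm_u12: PWM | None = None,
    donor_pwm_u2: PWM | None = None,
    params: U12Params | None = None,
) -> list[IntronClassification]:
    """Score every intron row of ``reference`` against the donor and
    branch-point matrices and assign U12/U2/unannotated classes.

    ``genome`` is a ``pyfaidx.Fasta`` (or any mapping of chromosome name to
    sliceable sequence).  Minus-strand introns are reverse-complemented so
    all windows are in transcription orientation.  The branch-point window is
    slid over the configured search region near the intron 3' end and the
    best-scoring offset kept, ties broken toward the 3' end.
    """
    pwms = default_pwms() if None in (donor_pwm_u12, bp_pwm_u12, donor_pwm_u2) else {}
    donor_pwm_u12 = donor_pwm_u12 or pwms["u12_donor"]
    bp_pwm_u12 = bp_pwm_u12 or pwms["u12_branchpoint"]
    donor_pwm_u2 = donor_pwm_u2 or pwms["u2_donor"]
    params = params or U12Params()
    bg = params.background

    introns = [r for r in reference if r.feature_kind == "intron"]
    missing = sorted({r.interval.chrom for r in introns} - set(_chrom_names(genome)))
    if missing:
        raise KeyError(f"chromosomes missing from genome FASTA: {missing}")

    d12_lo, d12_hi = _score_bounds(donor_pwm_u12, bg)
    bp_lo, bp_hi = _score_bounds(bp_pwm_u12, bg)
    d2_lo, d2_hi = _score_bounds(donor_pwm_u2, bg)

    out: list[IntronClassification] = []
    for row in introns:
        iv = row.interval
        seq = _intron_seq(genome, iv.chrom, iv.start, iv.end, iv.strand)
        L = len(seq)
        termini = (seq[:2], seq[-2:]) if L >= 4 else (seq[:2], seq[-2:])

        if L < donor_pwm_u12.n_cols + bp_pwm_u12.n_cols:
            out.append(IntronClassification(
                intron_key=row.intron_key,
                donor_score_u12=float("nan"), bp_score_u12=float("nan"),
                donor_score_u2=float("nan"), donor_rel_u12=float("nan"),
                bp_rel_u12=float("nan"), donor_rel_u2=float("nan"),
                best_bp_offset=None, assigned_class="unannotated",
                terminal_dinucleotides=termini, too_short=True,
            ))
            continue

        # Donor window anchored so that the anchor column sits on intron base 1.
        dw = donor_pwm_u12.n_cols
        donor_seq = seq[:dw]  # packaged donor matrices have anchor 0
        d12 = score_pwm(donor_pwm_u12, donor_seq, bg)
        d2_seq = seq[:donor_pwm_u2.n_cols]
        d2 = score_pwm(donor_pwm_u2, d2_seq, bg)

        # Slide the branch-point window; offsets are window starts relative to
        # the 3' end, restricted so the window stays inside the intron and
        # clear of the donor window.
        bw = bp_pwm_u12.n_cols
        best_bp = -np.inf
        best_off: int | None = None
        lo_off = max(params.bp_search_start, dw - L)
        hi_off = min(params.bp_search_end, -bw)
        for off in range(lo_off, hi_off + 1):  # ascending: later offsets win ties
            window = seq[L + off: L + off + bw]
            s = score_pwm(bp_pwm_u12, window, bg)
            if s >= best_bp:
                best_bp, best_off = s, off
        if best_off is None:
            bp = float("nan")
            bp_rel = float("nan")
        else:
            bp = best_bp
            bp_rel = (bp - bp_lo) / (bp_hi - bp_lo)

        d12_rel = (d12 - d12_lo) / (d12_hi - d12_lo)
        d2_rel = (d2 - d2_lo) / (d2_hi - d2_lo)

        if (best_off is not None and d12_rel >= params.donor_threshold
                and bp_rel >= params.bp_threshold):
            cls = "U12"
        elif termini in {("GT", "AG"), ("AT", "AC")}:
            cls = "U2"
        else:
            cls = "unannotated"

        out.append(IntronClassification(
            intron_key=row.intron_key,
            donor_score_u12=d12, bp_score_u12=bp, donor_score_u2=d2,
            donor_rel_u12=d12_rel, bp_rel_u12=bp_rel, donor_rel_u2=d2_rel,
            best_bp_offset=best_off, assigned_class=cls,
            terminal_dinucleotides=termini,
        ))
    return out


def _chrom_names(genome) -> list[str]:
    keys = getattr(genome, "keys", None)
    return list(keys()) if callable(keys) else list(genome)


def annotate_reference(
    reference: Sequence[ReferenceRow],
    classifications: Sequence[IntronClassification],
) -> list[ReferenceRow]:
    """Return reference rows with ``intron_class`` filled in from the
    classification results (exon rows pass through unchanged)."""
    from dataclasses import replace

    by_key = {c.intron_key: c.assigned_class for c in classifications}
    out = []
    for row in reference:
        if row.feature_kind == "intron" and row.intron_key in by_key:
            out.append(replace(row, intron_class=by_key[row.intron_key]))
        else:
            out.append(row)
    return out


def write_classification_tsv(
    classifications: Sequence[IntronClassification], path: str | Path
) -> None:
    cols = ["gene_id", "intron_ordinal", "donor_score_u12", "bp_score_u12",
            "donor_score_u2", "donor_rel_u12", "bp_rel_u12", "donor_rel_u2",
            "best_bp_offset", "class", "termini_5p", "termini_3p", "too_short"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for c in classifications:
            fh.write("\t".join([
                c.intron_key[0], str(c.intron_key[1]),
                f"{c.donor_score_u12:.4f}", f"{c.bp_score_u12:.4f}",
                f"{c.donor_score_u2:.4f}", f"{c.donor_rel_u12:.4f}",
                f"{c.bp_rel_u12:.4f}", f"{c.donor_rel_u2:.4f}",
                "" if c.best_bp_offset is None else str(c.best_bp_offset),
                c.assigned_class, c.terminal_dinucleotides[0],
                c.terminal_dinucleotides[1], str(c.too_short),
            ]) + "\n")
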