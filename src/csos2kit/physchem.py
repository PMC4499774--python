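"""Physicochemical computations on protein sequences.

Average-mass molecular weight, theoretical isoelectric point (Bjellqvist pK
set, bisection), residue composition, in-silico tryptic digestion with
sequence-coverage accounting, and the two small assay formulas used around
turbidity (ΔOD600) and circular dichroism (mean residue ellipticity).

All residue coordinates in this module are 1-based inclusive, the convention
used throughout protein annotation tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .records import ProteinRecord, InvalidSequenceError

# Average (isotope-abundance weighted) residue masses in Da, i.e. the mass of
# the amino acid minus one water; the free chain adds one water (18.0153 Da).
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.0153

# Bjellqvist pK values as used by the Expasy Compute pI/Mw tool.  Side-chain
# pKs plus free-terminus pKs; the N-terminal pK depends on the first residue.
PK_SIDECHAIN_NEG = {"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
PK_SIDECHAIN_POS = {"K": 10.0, "R": 12.0, "H": 5.98}
PK_NTERM_DEFAULT = 7.5
PK_NTERM = {"A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82, "V": 7.44, "E": 7.7}
PK_CTERM_DEFAULT = 3.55
PK_CTERM = {"D": 4.55, "E": 4.75}


def _clean(sequence: str) -> str:
    # X is only present when a record was built permissively; it carries no
    # mass or charge information and is skipped.
    return sequence.replace("X", "")


def compute_mw(rec: ProteinRecord) -> float:
    """Molecular weight in kDa from average residue masses plus one water."""
    seq = _clean(rec.sequence)
    try:
        total = sum(AVERAGE_RESIDUE_MASS[ch] for ch in seq) + WATER_MASS
    except KeyError as exc:  # defence in depth; records validate on entry
        ch = exc.args[0]
        raise InvalidSequenceError(
            f"{rec.id}: unknown residue {ch!r} at position {rec.sequence.index(ch) + 1}"
        ) from exc
    return total / 1000.0


def net_charge(sequence: str, ph: float) -> float:
    """Henderson–Hasselbalch net charge of a sequence at a given pH.

    Contributions: free N-terminus and C-terminus plus the D, E, C, Y
    (acidic) and H, K, R (basic) side chains, with the Bjellqvist pK set.
    """
    seq = _clean(sequence)
    if not seq:
        raise InvalidSequenceError("sequence has no chargeable residues")
    pos = 0.0
    neg = 0.0
    # termini
    pk_n = PK_NTERM.get(seq[0], PK_NTERM_DEFAULT)
    pos += 1.0 / (1.0 + 10.0 ** (ph - pk_n))
    pk_c = PK_CTERM.get(seq[-1], PK_CTERM_DEFAULT)
    neg += 1.0 / (1.0 + 10.0 ** (pk_c - ph))
    for ch in seq:
        if ch in PK_SIDECHAIN_POS:
            pk = PK_SIDECHAIN_POS[ch]
            pos += 1.0 / (1.0 + 10.0 ** (ph - pk))
        elif ch in PK_SIDECHAIN_NEG:
            pk = PK_SIDECHAIN_NEG[ch]
            neg += 1.0 / (1.0 + 10.0 ** (pk - ph))
    return pos - neg


def compute_pi(rec: ProteinRecord, *, charge_tol: float = 1e-4) -> float:
    """Theoretical isoelectric point by bisection on the net-charge curve.

    The charge is monotone decreasing in pH, so bisection on the bracket
    [0, 14] converges deterministically; iteration stops when the residual
    charge magnitude drops below ``charge_tol``.
    """
    lo, hi = 0.0, 14.0
    mid = 7.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        q = net_charge(rec.sequence, mid)
        if abs(q) < charge_tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return mid


def residue_counts(rec: ProteinRecord, residues) -> dict[str, int]:
    """Exact tallies of the requested residue codes."""
    residues = list(residues)
    bad = [r for r in residues if r not in AVERAGE_RESIDUE_MASS]
    if bad:
        raise ValueError(f"non-standard residue codes requested: {bad}")
    return {r: rec.sequence.count(r) for r in residues}


DEFAULT_COUNT_RESIDUES = ("C", "H", "R", "K", "E", "Q")


@dataclass(frozen=True)
class CompositionReport:
    """Length, MW (kDa), pI and selected residue counts for one protein."""

    length: int
    mw: float
    pi: float
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mw <= 0:
            raise ValueError("mw must be positive")
        if not (0.0 < self.pi < 14.0):
            raise ValueError("pI must lie strictly between 0 and 14")
        for code, n in self.counts.items():
            if not (0 <= n <= self.length):
                raise ValueError(f"count for {code} out of range")


def composition_report(
    rec: ProteinRecord, residues=DEFAULT_COUNT_RESIDUES
) -> CompositionReport:
    return CompositionReport(
        length=len(rec.sequence),
        mw=compute_mw(rec),
        pi=compute_pi(rec),
        counts=residue_counts(rec, residues),
    )


@dataclass(frozen=True)
class PeptideSpan:
    """A contiguous stretch of a parent protein, 1-based inclusive."""

    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError("require 1 <= start <= end")
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("span coordinates disagree with sequence length")

    def __len__(self) -> int:
        return self.end - self.start + 1


def tryptic_digest(rec: ProteinRecord, *, max_missed: int = 0) -> list[PeptideSpan]:
    """In-silico trypsin digest: cleave after K or R unless followed by P.

    With ``max_missed`` = 0 (default) the returned spans partition the
    sequence: contiguous, ordered and jointly covering every residue.
    Larger values additionally return peptides spanning up to that many
    missed cleavage sites (appended after the fully cleaved set).
    """
    seq = rec.sequence
    cut_after = [
        i
        for i in range(len(seq) - 1)
        if seq[i] in "KR" and seq[i + 1] != "P"
    ]
    bounds = [0] + [i + 1 for i in cut_after] + [len(seq)]
    base = [
        PeptideSpan(bounds[i] + 1, bounds[i + 1], seq[bounds[i] : bounds[i + 1]])
        for i in range(len(bounds) - 1)
    ]
    if max_missed <= 0:
        return base
    extra = []
    for miss in range(1, max_missed + 1):
        for i in range(len(base) - miss):
            start = base[i].start
            end = base[i + miss].end
            extra.append(PeptideSpan(start, end, seq[start - 1 : end]))
    return base + extra


def coverage_from_spans(length: int, spans) -> float:
    """Percent of residues 1..length covered by the union of the spans.

    Overlapping and duplicated spans count each residue once.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    covered = 0
    last_end = 0
    for span in sorted(spans, key=lambda s: (s.start, s.end)):
        if span.start < 1 or span.end > length:
            raise ValueError(
                f"span {span.start}-{span.end} outside sequence of length {length}"
            )
        lo = max(span.start, last_end + 1)
        if span.end >= lo:
            covered += span.end - lo + 1
            last_end = span.end
        last_end = max(last_end, span.end)
    return 100.0 * covered / length


@dataclass(frozen=True)
class MixingMeasurement:
    """Turbidity readings for a two-component mixing experiment."""

    od_mix: float
    od_a: float
    vol_a: float
    od_b: float
    vol_b: float

    def __post_init__(self) -> None:
        if self.vol_a <= 0 or self.vol_b <= 0:
            raise ValueError("volumes must be positive")
        if min(self.od_mix, self.od_a, self.od_b) < 0:
            raise ValueError("OD readings must be non-negative")


def delta_od600(m: MixingMeasurement) -> float:
    """Turbidity gain on mixing beyond the volume-weighted component mean.

    ΔOD600 = OD_mix − (OD_a·V_a + OD_b·V_b) / (V_a + V_b).  A positive value
    indicates precipitation/aggregation on mixing.
    """
    denom = m.vol_a + m.vol_b
    if denom == 0:
        raise ValueError("total volume must be positive")
    return m.od_mix - (m.od_a * m.vol_a + m.od_b * m.vol_b) / denom


@dataclass(frozen=True)
class CdMeasurement:
    """A circular-dichroism reading with the quantities needed to normalise it."""

    signal_mdeg: float
    mrw: float  # mean residue weight: molecular weight / number of backbone amides
    path_mm: float
    conc_mg_ml: float

    def __post_init__(self) -> None:
        if self.path_mm <= 0:
            raise ValueError("path length must be positive")
        if self.conc_mg_ml <= 0:
            raise ValueError("concentration must be positive")


def mean_residue_ellipticity(c: CdMeasurement) -> float:
    """[θ] in deg·cm²·dmol⁻¹ = signal[mdeg] × MRW / (path[mm] × conc[mg/mL])."""
    return c.signal_mdeg * c.mrw / (c.path_mm * c.conc_mg_ml)
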