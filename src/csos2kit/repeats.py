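"""Detection of N- and M-repeats in CsoS2-like scaffold proteins.

CsoS2-like proteins show a tripartite architecture: an N-terminal region
built of 16-residue repeats that open with a basic residue (R/K) followed by
an acidic one (E/D); a middle (M) region of ~50-residue repeats (one repeat
per protein is typically a 40-residue short form) that each contain three
3-residue units spaced eight residues apart (a period of 11 between unit
starts) and carry a cysteine signature near the repeat terminus (tandem CC,
single C, or none — coded T/S/N); and a ~170-residue C-terminal region.

The detectors here are rule/score based:

* M-repeats are found through triad periodicity — positions whose 3-mer
  recurs (BLOSUM62 score above a threshold) at +11 and +22 anchor a repeat
  unit.  The default score threshold (12) was chosen so that a random pair
  of 3-mers passes with probability ~3e-3, making a chance double
  recurrence (~8e-6 per position) vanishingly rare on protein-sized inputs.
* N-repeats are anchored 16-mer windows (R/K then E/D) accepted only when at
  least two candidate windows are mutually similar; the default pair-score
  threshold (40) sits more than six standard deviations above the random
  16-mer pair score (mean ≈ −17, sd ≈ 8.8 under BLOSUM62).

Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from Bio.Align import substitution_matrices

from .records import ProteinRecord
from .physchem import (
    CompositionReport,
    composition_report,
    compute_pi,
    DEFAULT_COUNT_RESIDUES,
)

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


class SegmentationError(ValueError):
    """Raised when the tripartite segmentation is undefined for a sequence."""


@dataclass(frozen=True)
class RepeatParams:
    """Tunable thresholds for the repeat detectors.

    The defaults encode the geometry described above; thresholds are set
    from the null score distributions of random peptides (see module
    docstring) so that chance hits are rare at protein scale.
    """

    # N-repeat detection
    n_length: int = 16
    n_min_pair_score: float = 40.0
    n_allow_exceptions: int = 1  # windows lacking the acidic second residue

    # M-repeat detection
    triad_len: int = 3
    triad_period: int = 11  # unit start to next unit start (3 aa + 8 aa gap)
    triad_offset: int = 5  # first triad start relative to repeat-unit start
    min_triad_score: float = 12.0
    triad_mode: str = "score"  # or "exact"
    min_anchor_gap: int = 30  # suppress competing anchors closer than this
    m_unit_long: int = 50
    m_unit_short: int = 40
    m_short_cutoff: int = 46  # anchor gap below this types the unit M_short
    cys_window: int = 15  # terminal window searched for the Cys signature

    # architecture summary
    c_intact_min: int = 100


DEFAULT_PARAMS = RepeatParams()


@dataclass(frozen=True)
class RepeatHit:
    """One located repeat, 1-based inclusive coordinates."""

    kind: str  # "N", "M_long" or "M_short"
    start: int
    end: int
    score: float
    triad_starts: tuple[int, ...] | None = None  # M-repeats only
    cys_signature: str | None = None  # "T", "S" or "N"; M-repeats only

    def __post_init__(self) -> None:
        if self.kind not in ("N", "M_long", "M_short"):
            raise ValueError(f"unknown repeat kind {self.kind!r}")
        if self.end < self.start:
            raise ValueError("end must be >= start")


@dataclass(frozen=True)
class RegionSegmentation:
    """Contiguous N/M/C split of residues 1..L."""

    n_region: tuple[int, int]
    m_region: tuple[int, int]
    c_region: tuple[int, int]

    def __post_init__(self) -> None:
        n, m, c = self.n_region, self.m_region, self.c_region
        if not (n[0] == 1 and n[1] + 1 == m[0] and m[1] + 1 == c[0]):
            raise ValueError("regions must be contiguous and ordered N, M, C")


@dataclass(frozen=True)
class ArchitectureSummary:
    """Per-protein report of repeat counts, signature and region properties."""

    record_id: str
    n_repeat_count: int
    m_repeat_count: int
    m_signature: str
    c_region_intact: bool
    regions: RegionSegmentation
    per_region_pi: tuple[float, float, float]
    composition: CompositionReport
    hits: tuple[RepeatHit, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.m_signature) != self.m_repeat_count:
            raise ValueError("signature length must equal M-repeat count")


def _pair_score(a: str, b: str) -> float:
    return float(sum(_BLOSUM62[x, y] for x, y in zip(a, b)))


def classify_cys_signature(window: str) -> str:
    """T if the window holds adjacent CC, S if any (non-tandem) C, else N."""
    if "CC" in window:
        return "T"
    if "C" in window:
        return "S"
    return "N"


def find_m_repeats(
    rec: ProteinRecord, params: RepeatParams = DEFAULT_PARAMS
) -> list[RepeatHit]:
    """Locate M-repeats by triad periodicity.

    Returns non-overlapping hits in sequence order; empty list when the
    sequence carries no periodic triads at the configured stringency.
    """
    seq = rec.sequence
    L = len(seq)
    t, p = params.triad_len, params.triad_period
    span = 2 * p + t  # residues needed to test one anchor
    if L < span:
        return []

    def triad(i: int) -> str:
        return seq[i : i + t]

    anchors: list[tuple[int, float]] = []  # (0-based pos, score)
    for i in range(L - span + 1):
        a, b, c = triad(i), triad(i + p), triad(i + 2 * p)
        if params.triad_mode == "exact":
            if a == b == c:
                anchors.append((i, 2.0 * _pair_score(a, a)))
        else:
            s1, s2 = _pair_score(a, b), _pair_score(a, c)
            if s1 >= params.min_triad_score and s2 >= params.min_triad_score:
                anchors.append((i, s1 + s2))

    # Suppress competing anchors that fall inside the same repeat unit:
    # within min_anchor_gap keep the higher score, leftmost on ties.
    accepted: list[tuple[int, float]] = []
    for pos, score in anchors:
        if accepted and pos - accepted[-1][0] < params.min_anchor_gap:
            if score > accepted[-1][1]:
                accepted[-1] = (pos, score)
            continue
        accepted.append((pos, score))

    hits: list[RepeatHit] = []
    prev_end = 0  # 1-based end of previous unit
    for j, (pos, score) in enumerate(accepted):
        start = max(pos - params.triad_offset + 1, prev_end + 1)  # 1-based
        if j + 1 < len(accepted):
            gap = accepted[j + 1][0] - pos
            unit_len = (
                params.m_unit_short if gap < params.m_short_cutoff else params.m_unit_long
            )
            # never run into the next unit
            next_start = accepted[j + 1][0] - params.triad_offset + 1
            end = min(start + unit_len - 1, next_start - 1)
        else:
            unit_len = params.m_unit_long
            end = min(start + unit_len - 1, L)
        if end - start + 1 < params.m_unit_short - 5:
            # degenerate sliver (clipped by sequence end or neighbour): drop
            continue
        kind = "M_short" if end - start + 1 <= params.m_unit_short + 2 else "M_long"
        window = seq[max(start - 1, end - params.cys_window) : end]
        hits.append(
            RepeatHit(
                kind=kind,
                start=start,
                end=end,
                score=score,
                triad_starts=(pos + 1, pos + 1 + p, pos + 1 + 2 * p),
                cys_signature=classify_cys_signature(window),
            )
        )
        prev_end = end
    return hits


def find_n_repeats(
    rec: ProteinRecord, params: RepeatParams = DEFAULT_PARAMS
) -> list[RepeatHit]:
    """Locate N-repeats: mutually similar 16-mer windows anchored R/K + E/D.

    A lone anchored window is not a repeat; acceptance requires at least two
    windows whose pairwise BLOSUM62 score reaches ``n_min_pair_score``.  Up
    to ``n_allow_exceptions`` windows missing the acidic second residue are
    admitted when they are similar to an accepted strict window.
    """
    seq = rec.sequence
    w = params.n_length
    if len(seq) < w:
        return []
    strict = []
    relaxed = []
    for i in range(len(seq) - w + 1):
        if seq[i] not in "RK":
            continue
        if seq[i + 1] in "ED":
            strict.append(i)
        else:
            relaxed.append(i)
    if len(strict) < 2 and not (strict and relaxed):
        return []

    def win(i: int) -> str:
        return seq[i : i + w]

    # mutual similarity among strict candidates
    best: dict[int, float] = {}
    for a in range(len(strict)):
        for b in range(a + 1, len(strict)):
            i, j = strict[a], strict[b]
            if abs(i - j) < w:
                continue  # overlapping windows do not certify each other
            s = _pair_score(win(i), win(j))
            if s > best.get(i, float("-inf")):
                best[i] = s
            if s > best.get(j, float("-inf")):
                best[j] = s
    accepted = {
        i: best[i] for i in strict if best.get(i, float("-inf")) >= params.n_min_pair_score
    }
    if not accepted:
        return []

    # soft E/D rule: rescue the best-scoring relaxed windows (limited number)
    rescues: list[tuple[float, int]] = []
    for i in relaxed:
        s = max(
            (
                _pair_score(win(i), win(j))
                for j in accepted
                if abs(i - j) >= w
            ),
            default=float("-inf"),
        )
        if s >= params.n_min_pair_score:
            rescues.append((s, i))
    rescues.sort(key=lambda t: (-t[0], t[1]))
    for s, i in rescues[: params.n_allow_exceptions]:
        accepted[i] = s

    # resolve overlaps: highest score wins, leftmost on ties
    chosen: list[tuple[int, float]] = []
    for i, s in sorted(accepted.items(), key=lambda t: (-t[1], t[0])):
        if all(abs(i - j) >= w for j, _ in chosen):
            chosen.append((i, s))
    chosen.sort()
    return [
        RepeatHit(kind="N", start=i + 1, end=i + w, score=s) for i, s in chosen
    ]


def segment_regions(rec: ProteinRecord, hits) -> RegionSegmentation:
    """Split the sequence into N/M/C regions from located repeats.

    The N/M boundary is the midpoint between the last N-repeat end and the
    first M-repeat start; the M/C boundary is the end of the last M-repeat.
    """
    n_hits = sorted((h for h in hits if h.kind == "N"), key=lambda h: h.start)
    m_hits = sorted((h for h in hits if h.kind.startswith("M")), key=lambda h: h.start)
    L = len(rec.sequence)
    if not n_hits or not m_hits:
        raise SegmentationError(
            f"{rec.id}: segmentation undefined — found {len(n_hits)} N-repeat(s) "
            f"and {len(m_hits)} M-repeat(s); both classes are required"
        )
    last_n_end = n_hits[-1].end
    first_m_start = m_hits[0].start
    if first_m_start <= last_n_end:
        raise SegmentationError(
            f"{rec.id}: M-repeats begin at {first_m_start}, before the last "
            f"N-repeat ends at {last_n_end}"
        )
    nm_boundary = (last_n_end + first_m_start) // 2
    mc_boundary = m_hits[-1].end
    if mc_boundary >= L:
        raise SegmentationError(f"{rec.id}: no residues remain for a C-region")
    return RegionSegmentation(
        n_region=(1, nm_boundary),
        m_region=(nm_boundary + 1, mc_boundary),
        c_region=(mc_boundary + 1, L),
    )


def summarize_architecture(
    rec: ProteinRecord,
    params: RepeatParams = DEFAULT_PARAMS,
    count_residues=DEFAULT_COUNT_RESIDUES,
) -> ArchitectureSummary:
    """Run both detectors, segment the sequence and compile a summary table row."""
    n_hits = find_n_repeats(rec, params)
    m_hits = find_m_repeats(rec, params)
    regions = segment_regions(rec, n_hits + m_hits)
    per_region_pi = tuple(
        compute_pi(rec.subrecord(lo, hi))
        for lo, hi in (regions.n_region, regions.m_region, regions.c_region)
    )
    c_len = regions.c_region[1] - regions.c_region[0] + 1
    return ArchitectureSummary(
        record_id=rec.id,
        n_repeat_count=len(n_hits),
        m_repeat_count=len(m_hits),
        m_signature="".join(h.cys_signature for h in m_hits),
        c_region_intact=c_len >= params.c_intact_min,
        regions=regions,
        per_region_pi=per_region_pi,
        composition=composition_report(rec, count_residues),
        hits=tuple(sorted(n_hits + m_hits, key=lambda h: h.start)),
    )
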