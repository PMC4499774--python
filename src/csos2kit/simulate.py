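"""Ground-truthed synthetic data: CsoS2-like sequences with planted repeat
architecture, and peptide-array spot tables with planted binding hotspots.

Every generator is a pure function of its parameters and seed, and returns
both the data and a truth object recording exactly what was planted, so
detector recovery can be scored against known answers.

Sequence model
--------------
The default geometry mirrors the tripartite scaffold: a 250-residue
N-region holding ``k_n`` 16-residue repeats (basic anchor then acidic
residue), a 350-residue M-region of one ~50-residue unit per signature
letter (a configurable subset, by default the third, in the 40-residue
short form) with period-11 triads and a terminal cysteine signature, and a
170-residue C-region.  Repeats are planted so that the last N-repeat and
the first M-unit sit symmetrically around the true N/M boundary, making the
midpoint segmentation rule identifiable.  Substitution noise is applied
inside repeats but never at anchor positions (the basic/acidic N-repeat
opening, the triads, the planted cysteines); cysteine is excluded from
random draws inside the terminal signature windows so the planted signature
stays the truth.

Array model
-----------
Spot signal = background_mean + amplitude·w(peptide) + ε with Gaussian ε,
where w is the hotspot profile (overlap fraction for "flat", linear ramp
for "triangular").  The per-spot SD is drawn log-normally around a
configurable coefficient of variation of the expected spot signal.
Negative signal draws are kept — background subtraction can legitimately
go negative, and such spots simply fail the 3σ detectability rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .records import ProteinRecord, STANDARD_AA
from .array import PeptideLibrary, SpotTable, build_library
from .repeats import RegionSegmentation

_AA = np.array(list(STANDARD_AA))
_AA_NO_C = np.array([a for a in STANDARD_AA if a != "C"])


@dataclass(frozen=True)
class SequenceTruth:
    """A generated sequence together with everything that was planted."""

    record: ProteinRecord
    n_repeat_spans: tuple[tuple[int, int], ...]
    m_repeat_spans: tuple[tuple[int, int], ...]
    m_signature: str
    region_boundaries: RegionSegmentation
    substitution_rate: float
    seed: int

    def to_json(self) -> str:
        d = {
            "record": {
                "id": self.record.id,
                "description": self.record.description,
                "sequence": self.record.sequence,
            },
            "n_repeat_spans": [list(s) for s in self.n_repeat_spans],
            "m_repeat_spans": [list(s) for s in self.m_repeat_spans],
            "m_signature": self.m_signature,
            "region_boundaries": {
                "n_region": list(self.region_boundaries.n_region),
                "m_region": list(self.region_boundaries.m_region),
                "c_region": list(self.region_boundaries.c_region),
            },
            "substitution_rate": self.substitution_rate,
            "seed": self.seed,
        }
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SequenceTruth":
        d = json.loads(text)
        return cls(
            record=ProteinRecord(**d["record"]),
            n_repeat_spans=tuple(tuple(s) for s in d["n_repeat_spans"]),
            m_repeat_spans=tuple(tuple(s) for s in d["m_repeat_spans"]),
            m_signature=d["m_signature"],
            region_boundaries=RegionSegmentation(
                n_region=tuple(d["region_boundaries"]["n_region"]),
                m_region=tuple(d["region_boundaries"]["m_region"]),
                c_region=tuple(d["region_boundaries"]["c_region"]),
            ),
            substitution_rate=d["substitution_rate"],
            seed=d["seed"],
        )


def _random_seq(rng, n: int, alphabet=_AA) -> list[str]:
    return list(rng.choice(alphabet, size=n))


def simulate_sequence(
    k_n: int = 4,
    m_signature: str = "TTNTTT",
    region_lengths: tuple[int, int, int] = (250, 350, 170),
    substitution_rate: float = 0.0,
    seed: int = 0,
    *,
    short_units: tuple[int, ...] = (3,),
    triad_offset: int = 5,
    triad_period: int = 11,
    n_length: int = 16,
    cys_window: int = 15,
    record_id: str = "synthetic_csos2",
) -> SequenceTruth:
    """Generate a CsoS2-like sequence with planted repeats and known truth."""
    if k_n < 0:
        raise ValueError("k_n must be >= 0")
    if any(ch not in "TSN" for ch in m_signature):
        raise ValueError("m_signature must be over {T, S, N}")
    if not (0.0 <= substitution_rate < 0.5):
        raise ValueError("substitution_rate must lie in [0, 0.5)")
    n_len, m_len, c_len = region_lengths
    rng = np.random.default_rng(seed)

    unit_lens = [
        40 if (i + 1) in short_units else 50 for i in range(len(m_signature))
    ]
    units_total = sum(unit_lens)
    lead = m_len - units_total  # spacer at the head of the M-region
    if m_signature and lead < 0:
        raise ValueError(
            f"M-region length {m_len} too small for {len(m_signature)} units "
            f"({units_total} residues)"
        )
    if not m_signature:
        lead = 0

    # ---- N-region -------------------------------------------------------
    n_seq = _random_seq(rng, n_len)
    n_spans: list[tuple[int, int]] = []
    anchor_positions: set[int] = set()  # 0-based absolute, noise-protected
    no_c_positions: set[int] = set()  # positions whose draws must avoid C
    if k_n > 0:
        # consensus repeat: basic anchor, acidic second, 14 random residues
        consensus = [str(rng.choice(list("RK"))), str(rng.choice(list("ED")))]
        consensus += _random_seq(rng, n_length - 2)
        # last repeat ends `lead` residues before the region end, mirroring
        # the first M-unit `lead` residues after it: midpoint-identifiable
        avail_end = n_len - lead
        if avail_end < k_n * n_length:
            raise ValueError(
                f"N-region length {n_len} too small for {k_n} repeats with "
                f"a {lead}-residue symmetric margin"
            )
        gap_total = avail_end - k_n * n_length
        gap = gap_total // k_n  # before each repeat; remainder enlarges gap 1
        starts = []
        pos = gap_total - gap * (k_n - 1)  # leading gap absorbs remainder
        for _ in range(k_n):
            starts.append(pos)
            pos += n_length + gap
        # shift so the last repeat is flush with avail_end
        shift = avail_end - (starts[-1] + n_length)
        starts = [s + shift for s in starts]
        for s in starts:
            n_seq[s : s + n_length] = consensus
            n_spans.append((s + 1, s + n_length))
            anchor_positions.update({s, s + 1})

    # ---- M-region -------------------------------------------------------
    m_seq = _random_seq(rng, lead)
    m_spans: list[tuple[int, int]] = []
    triad = _random_seq(rng, 3, _AA_NO_C)  # C-free: keeps signatures clean
    offset = lead
    for letter, ulen in zip(m_signature, unit_lens):
        unit = _random_seq(rng, ulen)
        win_start = ulen - cys_window
        for j in range(win_start, ulen):
            if unit[j] == "C":
                unit[j] = str(rng.choice(_AA_NO_C))
        for t_idx in range(3):
            p = triad_offset + t_idx * triad_period
            unit[p : p + 3] = triad
            anchor_positions.update(
                {n_len + offset + p + d for d in range(3)}
            )
        if letter == "T":
            unit[ulen - 5] = "C"
            unit[ulen - 4] = "C"
            anchor_positions.update({n_len + offset + ulen - 5, n_len + offset + ulen - 4})
        elif letter == "S":
            unit[ulen - 5] = "C"
            anchor_positions.add(n_len + offset + ulen - 5)
        no_c_positions.update(
            {n_len + offset + j for j in range(win_start, ulen)}
        )
        m_seq += unit
        m_spans.append((n_len + offset + 1, n_len + offset + ulen))
        offset += ulen

    # ---- C-region and assembly ------------------------------------------
    c_seq = _random_seq(rng, c_len)
    seq = n_seq + m_seq + c_seq

    # substitution noise inside planted repeats, anchors protected
    if substitution_rate > 0:
        mutable: list[int] = []
        for s, e in n_spans + m_spans:
            mutable.extend(
                p for p in range(s - 1, e) if p not in anchor_positions
            )
        flips = rng.random(len(mutable)) < substitution_rate
        for p, flip in zip(mutable, flips):
            if not flip:
                continue
            pool = _AA_NO_C if p in no_c_positions else _AA
            choices = [a for a in pool if a != seq[p]]
            seq[p] = str(rng.choice(choices))

    L = n_len + (lead + units_total if m_signature else 0) + c_len
    record = ProteinRecord(
        id=record_id,
        sequence="".join(seq),
        description=f"synthetic planted architecture seed={seed}",
    )
    assert len(record.sequence) == L
    m_end = n_len + m_len if m_signature else n_len
    regions = RegionSegmentation(
        n_region=(1, n_len),
        m_region=(n_len + 1, m_end),
        c_region=(m_end + 1, L),
    )
    return SequenceTruth(
        record=record,
        n_repeat_spans=tuple(n_spans),
        m_repeat_spans=tuple(m_spans),
        m_signature=m_signature,
        region_boundaries=regions,
        substitution_rate=substitution_rate,
        seed=seed,
    )


@dataclass(frozen=True)
class Hotspot:
    """A planted binding site on residue coordinates of the parent."""

    center: int  # residue position (1-based)
    width: int  # residues; default mirrors the 23-residue C-region site
    amplitude: float
    profile: str = "flat"  # or "triangular"

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.profile not in ("flat", "triangular"):
            raise ValueError(f"unknown profile {self.profile!r}")

    @property
    def span(self) -> tuple[int, int]:
        half = (self.width - 1) / 2.0
        return (int(np.ceil(self.center - half)), int(np.floor(self.center + half)))


@dataclass(frozen=True)
class ArrayTruth:
    library: PeptideLibrary
    hotspots: tuple[Hotspot, ...]
    background_mean: float
    background_sd: float
    spot_noise_sd: float
    replicates: int
    seed: int

    def to_json(self) -> str:
        d = {
            "library": {
                "parent_id": self.library.parent_id,
                "k": self.library.k,
                "step": self.library.step,
                "peptides": [[pid, seq] for pid, seq in self.library.peptides],
                "replicates": self.library.replicates,
            },
            "hotspots": [asdict(h) for h in self.hotspots],
            "background_mean": self.background_mean,
            "background_sd": self.background_sd,
            "spot_noise_sd": self.spot_noise_sd,
            "replicates": self.replicates,
            "seed": self.seed,
        }
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ArrayTruth":
        d = json.loads(text)
        lib = d["library"]
        return cls(
            library=PeptideLibrary(
                parent_id=lib["parent_id"],
                k=lib["k"],
                step=lib["step"],
                peptides=tuple((int(p), s) for p, s in lib["peptides"]),
                replicates=lib["replicates"],
            ),
            hotspots=tuple(Hotspot(**h) for h in d["hotspots"]),
            background_mean=d["background_mean"],
            background_sd=d["background_sd"],
            spot_noise_sd=d["spot_noise_sd"],
            replicates=d["replicates"],
            seed=d["seed"],
        )


def hotspot_weight(hotspot: Hotspot, peptide_start: int, k: int) -> float:
    """Profile weight w ∈ [0, 1] of a peptide against one hotspot."""
    pep_lo, pep_hi = peptide_start, peptide_start + k - 1
    lo, hi = hotspot.span
    if hotspot.profile == "flat":
        overlap = min(pep_hi, hi) - max(pep_lo, lo) + 1
        return max(overlap, 0) / k
    center = (pep_lo + pep_hi) / 2.0
    half = hotspot.width / 2.0
    return float(max(0.0, 1.0 - abs(center - hotspot.center) / half))


def simulate_array(
    library: PeptideLibrary,
    hotspots=(),
    *,
    assay_name: str = "synthetic_assay",
    background_mean: float = 100.0,
    background_sd: float = 10.0,
    spot_noise_sd: float = 10.0,
    sd_cv: float = 0.1,
    sd_lognorm_sigma: float = 0.3,
    replicates: int = 4,
    seed: int = 0,
) -> tuple[SpotTable, ArrayTruth]:
    """Simulate replicate spot intensities for one assay over a library."""
    hotspots = tuple(hotspots)
    rng = np.random.default_rng(seed)
    k = library.k
    ids = np.array(library.ids)
    amp = np.zeros(len(ids))
    for h in hotspots:
        w = np.array([hotspot_weight(h, int(pid), k) for pid in ids])
        amp = np.maximum(amp, h.amplitude * w)
    expected = background_mean + amp

    n_spots = len(ids) * replicates
    noise = rng.normal(0.0, spot_noise_sd, size=n_spots)
    mu = np.repeat(expected, replicates)
    signal = mu + noise
    spot_sd = sd_cv * mu * np.exp(
        rng.normal(0.0, sd_lognorm_sigma, size=n_spots)
    )
    data = pd.DataFrame(
        {
            "peptide_id": np.repeat(ids, replicates),
            "replicate": np.tile(np.arange(1, replicates + 1), len(ids)),
            "signal": signal,
            "spot_sd": spot_sd,
        }
    )
    table = SpotTable(
        assay_name=assay_name,
        data=data,
        background_mean=background_mean,
        background_sd=background_sd,
    )
    truth = ArrayTruth(
        library=library,
        hotspots=hotspots,
        background_mean=background_mean,
        background_sd=background_sd,
        spot_noise_sd=spot_noise_sd,
        replicates=replicates,
        seed=seed,
    )
    return table, truth


def random_protein(length: int, seed: int = 0, record_id: str = "random_protein") -> ProteinRecord:
    """A uniform-composition random protein, for null experiments."""
    rng = np.random.default_rng(seed)
    return ProteinRecord(
        id=record_id,
        sequence="".join(rng.choice(_AA, size=length)),
        description=f"uniform random seed={seed}",
    )
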