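"""Combined per-residue report: architecture plus per-assay hotspot marks."""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass

import pandas as pd

from .repeats import ArchitectureSummary


def render_position_map(
    summary: ArchitectureSummary,
    annotations=(),
    *,
    sequence: str | None = None,
    k: int = 8,
) -> pd.DataFrame:
    """One row per residue with region label, repeat membership and marks.

    ``annotations`` is an iterable of :class:`~csos2kit.array.HotspotAnnotation`;
    each assay contributes a mark/saturation column pair.  A marked peptide
    with id p flags residues p..p+k−1.
    """
    lo, hi = summary.regions.n_region[0], summary.regions.c_region[1]
    length = hi - lo + 1
    if sequence is not None and len(sequence) != length:
        raise ValueError(
            f"sequence length {len(sequence)} does not match regions (expect {length})"
        )
    region = ["N"] * (summary.regions.n_region[1]) + ["M"] * (
        summary.regions.m_region[1] - summary.regions.m_region[0] + 1
    ) + ["C"] * (summary.regions.c_region[1] - summary.regions.c_region[0] + 1)
    repeat = [""] * length
    for hit in summary.hits:
        for pos in range(hit.start, hit.end + 1):
            repeat[pos - 1] = hit.kind
    table = pd.DataFrame(
        {
            "position": range(1, length + 1),
            "region": region,
            "repeat": repeat,
        }
    )
    if sequence is not None:
        table.insert(1, "residue", list(sequence))
    for ann in annotations:
        mark_col = [""] * length
        sat_col = [float("nan")] * length
        for _, r in ann.marks.iterrows():
            pid = int(r["peptide_id"])
            if pid < 1 or pid + k - 1 > length:
                raise ValueError(
                    f"mark at peptide {pid} (k={k}) falls outside parent of "
                    f"length {length}: annotations do not match this protein"
                )
            for pos in range(pid, pid + k):
                mark_col[pos - 1] = str(r["mark_reason"])
                sat_col[pos - 1] = float(r["saturation_pct"])
        table[f"{ann.assay_name}_mark"] = mark_col
        table[f"{ann.assay_name}_saturation"] = sat_col
    return table


def write_effective_config(params, path, **extra) -> None:
    """Record the effective parameter set of a run next to its outputs."""
    payload = {}
    if is_dataclass(params):
        payload.update(asdict(params))
    elif isinstance(params, dict):
        payload.update(params)
    payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
        fh.write("\n")
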