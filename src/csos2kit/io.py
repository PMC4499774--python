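"""Format writers and small parsing helpers: GFF3, BED, key=value config.

Annotation coordinates are 1-based inclusive internally (and in GFF3);
BED output converts to 0-based half-open.
"""

from __future__ import annotations

from .repeats import ArchitectureSummary, RepeatHit

GFF_VERSION_LINE = "##gff-version 3"


def to_bed_interval(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    if start < 1 or end < start:
        raise ValueError(f"bad 1-based interval {start}-{end}")
    return start - 1, end


def from_bed_interval(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    if start0 < 0 or end0 <= start0:
        raise ValueError(f"bad 0-based interval {start0}-{end0}")
    return start0 + 1, end0


def _gff_feature_type(hit: RepeatHit) -> str:
    return "N_repeat" if hit.kind == "N" else "M_repeat"


def write_repeats_gff3(summary: ArchitectureSummary, path) -> None:
    """Repeat features plus region features as GFF3 on protein coordinates."""
    seqid = summary.record_id
    lines = [GFF_VERSION_LINE]
    for name, (lo, hi) in zip(
        ("N_region", "M_region", "C_region"),
        (
            summary.regions.n_region,
            summary.regions.m_region,
            summary.regions.c_region,
        ),
    ):
        lines.append(
            f"{seqid}\tcsos2kit\tregion\t{lo}\t{hi}\t.\t.\t.\tName={name}"
        )
    for i, hit in enumerate(summary.hits, start=1):
        attrs = [f"ID=repeat{i}", f"repeat_kind={hit.kind}"]
        if hit.cys_signature is not None:
            attrs.append(f"cys_signature={hit.cys_signature}")
        if hit.triad_starts is not None:
            attrs.append("triad_starts=" + ",".join(map(str, hit.triad_starts)))
        lines.append(
            f"{seqid}\tcsos2kit\t{_gff_feature_type(hit)}\t{hit.start}\t{hit.end}"
            f"\t{hit.score:.1f}\t.\t.\t{';'.join(attrs)}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_repeats_bed(summary: ArchitectureSummary, path) -> None:
    with open(path, "w") as fh:
        for hit in summary.hits:
            s0, e0 = to_bed_interval(hit.start, hit.end)
            name = hit.kind if hit.cys_signature is None else f"{hit.kind}:{hit.cys_signature}"
            fh.write(f"{summary.record_id}\t{s0}\t{e0}\t{name}\t{hit.score:.0f}\n")


def write_marks_bed(parent_id: str, marks, k: int, path) -> None:
    """Hotspot marks as a BED track; score = saturation × 10 (0-1000)."""
    with open(path, "w") as fh:
        for _, r in marks.iterrows():
            start = int(r["position"]) if "position" in r else int(r["peptide_id"])
            s0, e0 = to_bed_interval(start, start + k - 1)
            assay = r.get("assay", "")
            name = f"{assay}:{r['mark_reason']}" if assay else str(r["mark_reason"])
            score = int(round(float(r["saturation_pct"]) * 10))
            fh.write(f"{parent_id}\t{s0}\t{e0}\t{name}\t{score}\n")


def read_config(path) -> dict[str, str]:
    """Parse a minimal ``key = value`` config file; '#' starts a comment."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            out[key] = value
    return out
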