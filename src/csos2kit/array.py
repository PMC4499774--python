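"""Peptide tiling-array analysis: library construction, spot detectability,
replicate positivity, hotspot marking and saturation scoring.

The analysis follows the standard filtering cascade for tiling peptide
chips probed with a labelled protein:

1. a spot is *detectable* when its background-subtracted signal exceeds
   three background standard deviations AND its spot-level standard
   deviation divided by its signal stays below 0.5 (both strict);
2. a peptide is a *positive hit* when strictly more than half of its
   replicate spots are detectable;
3. a positive peptide is *marked* as a binding hotspot when its averaged
   intensity ranks in the top 10 among positives, or when it is a local
   maximum within a run of more than five sequential positive peptides;
4. every mark carries a *saturation* — its averaged intensity as a percent
   of the maximum averaged intensity among positives of the same assay.

Peptide ids equal the 1-based start position of the peptide in the parent
sequence, so ids map directly onto residue coordinates.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import ProteinRecord


@dataclass(frozen=True)
class PeptideLibrary:
    """An ordered k-mer tiling of a parent protein."""

    parent_id: str
    k: int
    step: int
    peptides: tuple[tuple[int, str], ...]  # (1-based start position, sequence)
    replicates: int = 4

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def __len__(self) -> int:
        return len(self.peptides)

    @property
    def ids(self) -> list[int]:
        return [pid for pid, _ in self.peptides]


def build_library(
    rec: ProteinRecord, k: int = 8, step: int = 1, replicates: int = 4
) -> PeptideLibrary:
    """Enumerate k-mer peptides at starts 1, 1+step, … along the parent."""
    L = len(rec.sequence)
    if k > L:
        raise ValueError(f"peptide length {k} exceeds sequence length {L}")
    if step < 1:
        raise ValueError("step must be >= 1")
    peptides = tuple(
        (start + 1, rec.sequence[start : start + k])
        for start in range(0, L - k + 1, step)
    )
    return PeptideLibrary(
        parent_id=rec.id, k=k, step=step, peptides=peptides, replicates=replicates
    )


SPOT_COLUMNS = ("peptide_id", "replicate", "signal", "spot_sd")


@dataclass
class SpotTable:
    """Replicate spot intensities for one binding assay.

    ``data`` holds one row per spot with columns peptide_id, replicate,
    signal and spot_sd (pixel-level standard deviation; may be NaN when the
    scanner did not report it).  Background statistics are per array.
    """

    assay_name: str
    data: pd.DataFrame
    background_mean: float
    background_sd: float

    def __post_init__(self) -> None:
        missing = [c for c in SPOT_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"spot table missing columns: {missing}")
        if self.background_sd <= 0:
            raise ValueError("background_sd must be positive")
        self.data = self.data.loc[:, list(SPOT_COLUMNS)].reset_index(drop=True)


def write_spot_table(table: SpotTable, path) -> None:
    """Write the documented CSV dialect: '#key=value' headers then rows."""
    with open(path, "w") as fh:
        fh.write(f"#assay={table.assay_name}\n")
        fh.write(f"#background_mean={table.background_mean!r}\n")
        fh.write(f"#background_sd={table.background_sd!r}\n")
        table.data.to_csv(fh, index=False)


def read_spot_table(path) -> SpotTable:
    meta: dict[str, str] = {}
    body_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                meta[key] = value
            else:
                body_lines.append(line)
    for key in ("assay", "background_mean", "background_sd"):
        if key not in meta:
            raise ValueError(f"spot table {path} lacks required header '#{key}='")
    data = pd.read_csv(io.StringIO("".join(body_lines)))
    return SpotTable(
        assay_name=meta["assay"],
        data=data,
        background_mean=float(meta["background_mean"]),
        background_sd=float(meta["background_sd"]),
    )


def call_detectable(
    signal: float, spot_sd: float, background_mean: float, background_sd: float
) -> bool:
    """Spot detectability: 3σ background rule and relative-noise rule.

    True iff (signal − background_mean) > 3·background_sd and
    spot_sd / signal < 0.5, both strict.  A non-positive signal fails the
    second condition outright (no division error escapes).
    """
    if background_sd <= 0:
        raise ValueError("background_sd must be positive")
    if signal - background_mean <= 3.0 * background_sd:
        return False
    if signal <= 0:
        return False
    return spot_sd / signal < 0.5


def hit_table(
    table: SpotTable,
    *,
    mean_mode: str = "all",
    sd_mode: str = "spot",
) -> pd.DataFrame:
    """Per-peptide positivity calls and averaged background-subtracted signal.

    ``mean_mode``: "all" averages every replicate (default); "detectable"
    averages detectable replicates only (falling back to all replicates for
    peptides with none detectable).  ``sd_mode``: "spot" uses the per-spot
    pixel SD from the data; "replicate" substitutes the replicate-level SD
    of the signals within each peptide (also used per spot when the spot SD
    is missing).
    """
    if mean_mode not in ("all", "detectable"):
        raise ValueError(f"unknown mean_mode {mean_mode!r}")
    if sd_mode not in ("spot", "replicate"):
        raise ValueError(f"unknown sd_mode {sd_mode!r}")
    df = table.data.copy()
    rep_sd = df.groupby("peptide_id")["signal"].transform("std").fillna(0.0)
    if sd_mode == "replicate":
        df["effective_sd"] = rep_sd
    else:
        df["effective_sd"] = df["spot_sd"].where(df["spot_sd"].notna(), rep_sd)

    sub = df["signal"] - table.background_mean
    cond1 = sub > 3.0 * table.background_sd
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(df["signal"] > 0, df["effective_sd"] / df["signal"], np.inf)
    df["detectable"] = cond1 & (ratio < 0.5)
    df["sub_signal"] = sub

    grouped = df.groupby("peptide_id", sort=True)
    out = grouped.agg(
        n_detectable=("detectable", "sum"),
        n_replicates=("detectable", "size"),
        mean_all=("sub_signal", "mean"),
    ).reset_index()
    if mean_mode == "detectable":
        det_mean = (
            df[df["detectable"]].groupby("peptide_id")["sub_signal"].mean()
        )
        out["mean_signal"] = out["peptide_id"].map(det_mean).fillna(out["mean_all"])
    else:
        out["mean_signal"] = out["mean_all"]
    out["positive"] = out["n_detectable"] > out["n_replicates"] / 2.0
    return out[["peptide_id", "mean_signal", "n_detectable", "n_replicates", "positive"]]


def call_positive(spots: pd.DataFrame, background_mean: float, background_sd: float):
    """Positivity call for a single peptide's replicate spots.

    Convenience wrapper over :func:`hit_table` semantics for one peptide;
    returns the single hit-table row as a Series.
    """
    table = SpotTable(
        assay_name="single",
        data=spots,
        background_mean=background_mean,
        background_sd=background_sd,
    )
    rows = hit_table(table)
    if len(rows) != 1:
        raise ValueError("call_positive expects spots for exactly one peptide")
    return rows.iloc[0]


@dataclass(frozen=True)
class HotspotAnnotation:
    """Marked peptides for one assay."""

    assay_name: str
    marks: pd.DataFrame  # peptide_id, mark_reason, mean_signal, saturation_pct

    def __len__(self) -> int:
        return len(self.marks)


MARK_COLUMNS = ("peptide_id", "mark_reason", "mean_signal", "saturation_pct")


def annotate_hotspots(
    hits: pd.DataFrame,
    *,
    assay_name: str = "",
    step: int = 1,
    top_n: int = 10,
    min_run: int = 6,
) -> HotspotAnnotation:
    """Mark hotspot peptides among the positives of one assay.

    Two mark reasons:

    * ``top10`` — the ``top_n`` highest averaged intensities among positive
      peptides (ties broken toward the lower peptide id);
    * ``local_max_run`` — inside every maximal run of step-adjacent positive
      peptides of length >= ``min_run``, each peptide strictly greater than
      its run neighbours (run endpoints compare against their single
      neighbour; plateaus are marked at their leftmost element).

    A peptide earning both reasons is reported once, as ``top10``.
    Saturation is the peptide's averaged intensity as a percent of the
    maximum averaged intensity among positives.
    """
    pos = hits[hits["positive"]].sort_values("peptide_id").reset_index(drop=True)
    if pos.empty:
        return HotspotAnnotation(assay_name, pd.DataFrame(columns=list(MARK_COLUMNS)))
    max_signal = pos["mean_signal"].max()
    if max_signal <= 0:
        # degenerate: positives with non-positive averaged signal; saturation
        # is undefined, nothing sensible to rank
        return HotspotAnnotation(assay_name, pd.DataFrame(columns=list(MARK_COLUMNS)))

    ranked = pos.sort_values(
        ["mean_signal", "peptide_id"], ascending=[False, True]
    )
    top_ids = set(ranked["peptide_id"].head(top_n))

    # maximal runs of step-adjacent positive peptides
    local_max_ids: set[int] = set()
    ids = pos["peptide_id"].to_numpy()
    sig = pos["mean_signal"].to_numpy()
    run_start = 0
    for idx in range(1, len(ids) + 1):
        if idx == len(ids) or ids[idx] - ids[idx - 1] != step:
            run = slice(run_start, idx)
            run_ids, run_sig = ids[run], sig[run]
            if len(run_ids) >= min_run:
                for j in range(len(run_ids)):
                    left_ok = j == 0 or run_sig[j] > run_sig[j - 1]
                    kk = j + 1
                    while kk < len(run_ids) and run_sig[kk] == run_sig[j]:
                        kk += 1
                    right_ok = kk >= len(run_ids) or run_sig[j] > run_sig[kk]
                    # plateau rule: left_ok forces the leftmost plateau element
                    if left_ok and right_ok:
                        local_max_ids.add(int(run_ids[j]))
            run_start = idx

    rows = []
    for _, r in pos.iterrows():
        pid = int(r["peptide_id"])
        if pid in top_ids:
            reason = "top10"
        elif pid in local_max_ids:
            reason = "local_max_run"
        else:
            continue
        rows.append(
            {
                "peptide_id": pid,
                "mark_reason": reason,
                "mean_signal": float(r["mean_signal"]),
                "saturation_pct": 100.0 * float(r["mean_signal"]) / max_signal,
            }
        )
    marks = pd.DataFrame(rows, columns=list(MARK_COLUMNS))
    return HotspotAnnotation(assay_name, marks)


@dataclass
class AssayReport:
    """Per-assay hit tables and hotspot marks plus a merged position map."""

    library: PeptideLibrary
    hit_tables: dict[str, pd.DataFrame]
    annotations: dict[str, HotspotAnnotation]
    merged: pd.DataFrame  # position, assay, mark_reason, saturation_pct


def assay_report(
    library: PeptideLibrary,
    spot_tables,
    *,
    mean_mode: str = "all",
    sd_mode: str = "spot",
    top_n: int = 10,
    min_run: int = 6,
) -> AssayReport:
    """Run the full calling cascade for one or more assays over one library."""
    lib_ids = set(library.ids)
    hit_tables: dict[str, pd.DataFrame] = {}
    annotations: dict[str, HotspotAnnotation] = {}
    merged_rows = []
    for table in spot_tables:
        extra = set(table.data["peptide_id"]) - lib_ids
        if extra:
            raise ValueError(
                f"assay {table.assay_name!r} references peptide ids not in the "
                f"library (e.g. {sorted(extra)[:3]})"
            )
        hits = hit_table(table, mean_mode=mean_mode, sd_mode=sd_mode)
        ann = annotate_hotspots(
            hits,
            assay_name=table.assay_name,
            step=library.step,
            top_n=top_n,
            min_run=min_run,
        )
        hit_tables[table.assay_name] = hits
        annotations[table.assay_name] = ann
        for _, r in ann.marks.iterrows():
            merged_rows.append(
                {
                    "position": int(r["peptide_id"]),
                    "assay": table.assay_name,
                    "mark_reason": r["mark_reason"],
                    "saturation_pct": r["saturation_pct"],
                }
            )
    merged = pd.DataFrame(
        merged_rows, columns=["position", "assay", "mark_reason", "saturation_pct"]
    )
    return AssayReport(
        library=library, hit_tables=hit_tables, annotations=annotations, merged=merged
    )
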