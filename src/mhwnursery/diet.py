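"""Stomach-content metrics: fullness and prey-specific diet composition.

The prey-specific index of relative importance for taxon *i* combines the
percent frequency of occurrence with prey-specific percent number and
percent weight (each averaged only over the stomachs that contain *i*):

    %PSIRI_i = %FO_i * (%PN_i + %PW_i) / (2 * 100)

so that the index sums to 100% over all taxa.  Abiotic items and empty
stomachs are removed before composition analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StomachRecord",
    "DietComposition",
    "stomach_fullness",
    "psiri",
    "apply_grouping_threshold",
    "empty_stomach_summary",
    "records_from_table",
    "composition_matrix",
]

OTHER_GROUP = "Other"


@dataclass
class StomachRecord:
    fish_id: str
    items: list[tuple[str, float, float]]  # (taxon, count, weight_mg)
    stomach_content_weight_g: float = 0.0
    fish_total_weight_g: float = np.nan
    abiotic_taxa: frozenset[str] = frozenset()

    @property
    def is_empty(self) -> bool:
        return not any(t not in self.abiotic_taxa for t, _, _ in self.items)

    def prey_items(self) -> list[tuple[str, float, float]]:
        return [it for it in self.items if it[0] not in self.abiotic_taxa]


@dataclass
class DietComposition:
    """Per-taxon composition table with %FO, %PN, %PW and %PSIRI columns."""

    table: pd.DataFrame
    n_stomachs: int
    grouping: dict[str, str] = field(default_factory=dict)

    @property
    def psiri(self) -> pd.Series:
        return self.table["psiri_pct"]


def stomach_fullness(rec: StomachRecord, sqrt_transform: bool = False) -> float:
    """Stomach content weight relative to somatic (content-free) weight."""
    content = rec.stomach_content_weight_g
    total = rec.fish_total_weight_g
    if not np.isfinite(total) or total <= content:
        raise ValueError(
            f"fish {rec.fish_id}: content weight {content} not below total {total}"
        )
    f = content / (total - content)
    return float(np.sqrt(f)) if sqrt_transform else float(f)


def _per_stomach_fractions(rec: StomachRecord, grouping: dict[str, str] | None):
    """Within-stomach count and weight fractions per (possibly grouped) taxon."""
    items = rec.prey_items()
    taxa = [grouping.get(t, t) if grouping else t for t, _, _ in items]
    counts = np.array([c for _, c, _ in items], float)
    weights = np.array([w for _, _, w in items], float)
    df = pd.DataFrame({"taxon": taxa, "count": counts, "weight": weights})
    agg = df.groupby("taxon", sort=False).sum()
    tc, tw = agg["count"].sum(), agg["weight"].sum()
    frac_n = agg["count"] / tc if tc > 0 else agg["count"] * 0.0
    frac_w = agg["weight"] / tw if tw > 0 else agg["weight"] * 0.0
    return frac_n, frac_w


def psiri(
    stomachs: list[StomachRecord], grouping: dict[str, str] | None = None
) -> DietComposition:
    """Prey-specific index of relative importance over non-empty stomachs.

    %PN_i / %PW_i are the mean within-stomach count / weight percentages
    of taxon *i* across stomachs containing *i*; %FO_i is the percentage
    of analyzed stomachs containing *i*.  Rows sum to 100% PSIRI.
    An optional ``grouping`` map collapses taxa before computation.
    """
    nonempty = [s for s in stomachs if not s.is_empty]
    if not nonempty:
        raise ValueError("all stomachs empty: diet composition undefined")
    n = len(nonempty)
    pn_sums: dict[str, float] = {}
    pw_sums: dict[str, float] = {}
    occ: dict[str, int] = {}
    for rec in nonempty:
        frac_n, frac_w = _per_stomach_fractions(rec, grouping)
        for taxon in frac_n.index:
            pn_sums[taxon] = pn_sums.get(taxon, 0.0) + float(frac_n[taxon])
            pw_sums[taxon] = pw_sums.get(taxon, 0.0) + float(frac_w[taxon])
            occ[taxon] = occ.get(taxon, 0) + 1
    taxa = sorted(occ)
    fo = np.array([100.0 * occ[t] / n for t in taxa])
    pn = np.array([100.0 * pn_sums[t] / occ[t] for t in taxa])
    pw = np.array([100.0 * pw_sums[t] / occ[t] for t in taxa])
    ps = fo * (pn + pw) / 200.0
    table = pd.DataFrame(
        {"taxon": taxa, "fo_pct": fo, "pn_pct": pn, "pw_pct": pw, "psiri_pct": ps}
    ).set_index("taxon")
    return DietComposition(table=table, n_stomachs=n, grouping=dict(grouping or {}))


def apply_grouping_threshold(
    stomachs: list[StomachRecord],
    comp: DietComposition,
    threshold: float = 3.5,
) -> DietComposition:
    """Merge taxa with PSIRI at or below ``threshold`` percent into "Other"
    and recompute the composition on the merged groups."""
    keep = set(comp.table.index[comp.table["psiri_pct"] > threshold])
    grouping = {t: (t if t in keep else OTHER_GROUP) for t in comp.table.index}
    if comp.grouping:  # compose with any earlier merge
        grouping = {
            raw: grouping.get(grp, grp) for raw, grp in comp.grouping.items()
        } | grouping
    return psiri(stomachs, grouping)


def empty_stomach_summary(
    stomachs: list[StomachRecord],
    strata: pd.DataFrame | None = None,
) -> dict:
    """Counts and percentage of empty stomachs, optionally stratified.

    ``strata``: fish_id-indexed frame with grouping columns (e.g. month,
    class); per-stratum summaries are included under "by_stratum".
    """
    n = len(stomachs)
    empties = [s.fish_id for s in stomachs if s.is_empty]
    out = {
        "n_stomachs": n,
        "n_empty": len(empties),
        "percent_empty": 100.0 * len(empties) / n if n else 0.0,
    }
    if strata is not None and n:
        flags = pd.Series(
            [s.is_empty for s in stomachs], index=[s.fish_id for s in stomachs]
        )
        joined = strata.copy()
        joined["_empty"] = flags.reindex(joined.index)
        by = (
            joined.groupby(list(strata.columns))["_empty"]
            .agg(n_empty="sum", n="count")
            .assign(percent_empty=lambda d: 100.0 * d["n_empty"] / d["n"])
        )
        out["by_stratum"] = by
        if out["n_empty"]:
            out["percent_of_empties_by_stratum"] = (
                100.0 * by["n_empty"] / out["n_empty"]
            )
    return out


def records_from_table(
    stomach: pd.DataFrame, abiotic_taxa: set[str] | None = None
) -> list[StomachRecord]:
    """Build StomachRecords from the long stomach.csv table.

    Empty stomachs appear as rows with a missing/blank prey_taxon.
    """
    abiotic = frozenset(abiotic_taxa or set())
    recs = []
    for fid, grp in stomach.groupby("fish_id", sort=True):
        items = [
            (str(r.prey_taxon), float(r.count), float(r.weight_mg))
            for r in grp.itertuples()
            if isinstance(r.prey_taxon, str) and r.prey_taxon != ""
        ]
        recs.append(
            StomachRecord(
                fish_id=str(fid),
                items=items,
                stomach_content_weight_g=float(grp["stomach_total_g"].iloc[0]),
                fish_total_weight_g=float(grp["fish_total_g"].iloc[0]),
                abiotic_taxa=abiotic,
            )
        )
    return recs


def composition_matrix(
    stomachs: list[StomachRecord], grouping: dict[str, str] | None = None
) -> pd.DataFrame:
    """Per-stomach PSIRI-style composition matrix (rows sum to 100).

    For a single stomach %FO is degenerate, so each row is the mean of the
    within-stomach count and weight percentages per group — the per-sample
    quantity whose average across stomachs reproduces the pooled PSIRI.
    """
    nonempty = [s for s in stomachs if not s.is_empty]
    if not nonempty:
        raise ValueError("all stomachs empty")
    rows = {}
    for rec in nonempty:
        frac_n, frac_w = _per_stomach_fractions(rec, grouping)
        rows[rec.fish_id] = 100.0 * (frac_n + frac_w) / 2.0
    mat = pd.DataFrame(rows).T.fillna(0.0)
    mat.index.name = "fish_id"
    return mat[sorted(mat.columns)]
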