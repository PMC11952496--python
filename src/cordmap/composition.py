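"""Cell-type composition and genotype comparison.

Per biological replicate, predicted cell-type counts are tabulated from
complete sections or complete hemisections only (a hemisection counts as
0.5), normalized to the number of sections collected for that replicate,
and expressed as proportions of all neurons.  Selected cell-type frequencies
are compared across genotypes in a two-way ANOVA (cell type x genotype, with
interaction) followed by Tukey's multiple-comparisons test between all
genotypes within each cell type.

Control datasets can be downsampled to mutant size: with ratio
rho = target_total / reference_total each cell type keeps
round(rho * n_k) cells (round half to even), sampled without replacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

ZONES = ("C1-C4", "C5-C8", "Thoracic", "L1-L3", "L4-L6/Sacral")


def build_composition(
    cells: pd.DataFrame,
    sections: pd.DataFrame,
    type_col: str = "cell_type",
) -> pd.DataFrame:
    """Composition table per (genotype, replicate, cell type).

    ``sections`` inventories complete (hemi)sections as rows of
    (replicate, section_id, weight) with weight 1.0 for a whole section and
    0.5 for a hemisection; cells from unlisted sections are excluded.
    Columns: raw ``count``, ``sections`` counted, per-section ``normalized``
    count, and ``proportion`` of all neurons in the replicate.
    """
    sec_weights = sections.groupby("replicate")["weight"].sum()
    if (sec_weights <= 0).any():
        bad = sec_weights[sec_weights <= 0].index.tolist()
        raise ValueError(f"replicates with zero complete sections: {bad}")
    complete_ids = set(sections["section_id"])
    kept = cells[cells["section_id"].isin(complete_ids)]
    counts = (
        kept.groupby(["genotype", "replicate", type_col], as_index=False)
        .size()
        .rename(columns={"size": "count", type_col: "cell_type"})
    )
    counts["sections"] = counts["replicate"].map(sec_weights)
    counts["normalized"] = counts["count"] / counts["sections"]
    totals = counts.groupby("replicate")["count"].transform("sum")
    counts["proportion"] = counts["count"] / totals
    return counts


def downsample_to_match(
    reference_cells: pd.DataFrame,
    target_total: int,
    seed: int,
    type_col: str = "cell_type",
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Downsample a reference (control) cell table to a mutant's total.

    Keeps round(rho * n_k) cells per type (rho = target/reference ratio,
    round half to even), sampled without replacement.  Returns the sampled
    table and an info dict with the achieved total per type and overall.
    """
    n_ref = len(reference_cells)
    if target_total > n_ref:
        raise ValueError("target_total exceeds the reference cell count")
    rho = target_total / n_ref
    rng = np.random.default_rng(seed)
    parts = []
    per_type: Dict[str, int] = {}
    for cell_type, sub in reference_cells.groupby(type_col, sort=True):
        keep = int(np.rint(rho * len(sub)))
        idx = rng.choice(len(sub), size=keep, replace=False)
        parts.append(sub.iloc[np.sort(idx)])
        per_type[cell_type] = keep
    out = pd.concat(parts, ignore_index=True) if parts else reference_cells.iloc[:0]
    info = {"achieved_total": len(out), "target_total": target_total, **per_type}
    return out, info


@dataclass(frozen=True)
class GenotypeComparisonResults:
    """Two-way ANOVA table plus per-cell-type Tukey pairwise comparisons."""

    anova: pd.DataFrame = field(repr=False)
    tukey: pd.DataFrame = field(repr=False)  # cell_type, g1, g2, meandiff, p_adj, reject
    response: str

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.tukey[self.tukey["p_adj"] < alpha]

    def summary(self) -> str:
        lines = [
            f"Two-way ANOVA (cell type x genotype), response = {self.response}",
            self.anova.to_string(),
            "",
            "Tukey pairwise comparisons within each cell type:",
        ]
        for row in self.tukey.itertuples():
            stars = (
                "***" if row.p_adj < 0.001
                else "**" if row.p_adj < 0.01
                else "*" if row.p_adj < 0.05
                else "ns"
            )
            lines.append(
                f"  {row.cell_type:>12s}  {row.group1} vs {row.group2}: "
                f"diff={row.meandiff:8.3f}  p={row.p_adj:.4f} {stars}"
            )
        return "\n".join(lines)


class CompositionComparison:
    """Genotype comparison model over a composition table.

    Parameters
    ----------
    table : DataFrame
        Output of :func:`build_composition`.
    cell_types : sequence, optional
        Subset of cell types to compare (default: all).
    response : str
        ``"normalized"`` (per-section-normalized counts, default) or
        ``"proportion"``.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        cell_types: Optional[Sequence[str]] = None,
        response: str = "normalized",
    ):
        if response not in ("normalized", "proportion"):
            raise ValueError("response must be 'normalized' or 'proportion'")
        data = table.copy()
        if cell_types is not None:
            data = data[data["cell_type"].isin(cell_types)]
        genotypes = data["genotype"].unique()
        if len(genotypes) < 2:
            raise ValueError("need at least two genotypes to compare")
        reps = data.groupby("genotype")["replicate"].nunique()
        if (reps < 2).any():
            raise ValueError(
                f"need >=2 replicates per genotype, got {reps.to_dict()}"
            )
        self.data = data
        self.response = response

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, **kwargs) -> "CompositionComparison":
        return cls(table, **kwargs)

    def fit(self) -> GenotypeComparisonResults:
        df = self.data.rename(columns={self.response: "y"})
        model = smf.ols("y ~ C(cell_type) * C(genotype)", data=df).fit()
        anova = sm.stats.anova_lm(model, typ=2)
        rows = []
        for cell_type, sub in df.groupby("cell_type", sort=True):
            if sub["genotype"].nunique() < 2:
                continue
            res = pairwise_tukeyhsd(sub["y"], sub["genotype"], alpha=0.05)
            groups = list(res.groupsunique)
            pairs = list(combinations(range(len(groups)), 2))
            for (i, j), md, p, rej in zip(
                pairs, res.meandiffs, res.pvalues, res.reject
            ):
                rows.append(
                    {
                        "cell_type": cell_type,
                        "group1": groups[i],
                        "group2": groups[j],
                        "meandiff": float(md),
                        "p_adj": float(p),
                        "reject": bool(rej),
                    }
                )
        tukey = pd.DataFrame(rows)
        return GenotypeComparisonResults(anova=anova, tukey=tukey, response=self.response)


def compare_genotypes(
    table: pd.DataFrame,
    cell_types: Optional[Sequence[str]] = None,
    response: str = "normalized",
) -> GenotypeComparisonResults:
    """Functional front door for :class:`CompositionComparison`."""
    return CompositionComparison(table, cell_types=cell_types, response=response).fit()


def zone_proportions(
    cells: pd.DataFrame,
    sections: pd.DataFrame,
    type_col: str = "cell_type",
) -> pd.DataFrame:
    """Per-embryo, per-zone cell-type fractions under the complete-section rule.

    ``cells`` rows carry embryo, segment_zone, section_id and a type label;
    fractions are of all neurons from the complete (hemi)sections of that
    embryo and zone.
    """
    unknown = set(cells["segment_zone"].dropna().unique()) - set(ZONES)
    if unknown:
        raise ValueError(f"unknown segment zones: {sorted(unknown)}")
    kept = cells[cells["section_id"].isin(set(sections["section_id"]))]
    counts = (
        kept.groupby(["embryo", "segment_zone", type_col], as_index=False)
        .size()
        .rename(columns={"size": "count", type_col: "cell_type"})
    )
    totals = counts.groupby(["embryo", "segment_zone"])["count"].transform("sum")
    counts["fraction"] = counts["count"] / totals
    return counts
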