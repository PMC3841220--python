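"""Top-k selection and the statistics used to validate the ranking.

Two checks mirror how the scoring method is evaluated:

* For each mapping, the mean EiC (and mean ED) of the top-k antibodies by
  score is compared against the population mean over all tested antibodies
  of that mapping with a one-sample t-test, one-sided ("greater") by
  default — the claim under test is that top-ranked antibodies capture
  proteins abundant (EiC) and overexpressed (ED) in the cancer.

* A specificity heat map: cell (i, j) is the mean ED on mapping i of the
  top-k antibodies selected for mapping j, with a trailing "All" column of
  population ED means.  Mapping-specific rankings show a dark diagonal —
  antibodies selected for a mapping are overexpressed there and near the
  population mean elsewhere.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import t as student_t

from .annotations_io import MappingDef
from .scoring_engine import EDMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "TTestResult",
    "top_k",
    "one_sample_t_test",
    "validate_topk_means",
    "ed_heatmap",
    "write_validation",
    "write_heatmap",
    "render_heatmap",
]

ALL_COLUMN = "All"


@dataclass(frozen=True)
class TTestResult:
    """One-sample t-test of a sample mean against a known population mean."""

    sample_mean: float
    sample_sd: float  # sample convention, N-1
    population_mean: float
    n: int
    t_statistic: float
    p_value: float
    alternative: str  # "greater" | "two_sided"


def one_sample_t_test(
    sample: Sequence[float],
    population_mean: float,
    alternative: str = "greater",
) -> TTestResult:
    """t = (x̄ - μ0) / (s / √n) with n-1 degrees of freedom.

    ``alternative="greater"`` tests whether the sample mean exceeds the
    population mean (the directional claim made for top-k antibodies);
    ``"two_sided"`` is available as well.
    """
    x = np.asarray(sample, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError(f"one-sample t-test needs n >= 2, got n = {n}")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0:
        raise ValueError("one-sample t-test undefined for zero sample SD")
    t_stat = (mean - population_mean) / (sd / np.sqrt(n))
    if alternative == "greater":
        p = float(student_t.sf(t_stat, df=n - 1))
    elif alternative == "two_sided":
        p = float(2 * student_t.sf(abs(t_stat), df=n - 1))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return TTestResult(mean, sd, float(population_mean), n, float(t_stat), p, alternative)


def top_k(scores: pd.DataFrame, mapping_id: str, k: int = 100) -> list[str]:
    """The k highest-scoring antibody ids of one mapping, best first.

    If fewer than k antibodies were scored for the mapping, all of them are
    returned with a warning.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    sub = scores[scores["mapping_id"] == mapping_id]
    if sub.empty:
        raise KeyError(f"no scores for mapping {mapping_id!r}")
    sub = sub.sort_values("rank")
    if len(sub) < k:
        warnings.warn(
            f"mapping {mapping_id!r}: only {len(sub)} scored antibodies "
            f"(k = {k} requested)",
            stacklevel=2,
        )
    return sub["antibody_id"].head(k).tolist()


def validate_topk_means(
    scores: pd.DataFrame,
    k: int = 100,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Per-mapping t-tests of top-k EiC and ED means vs population means.

    Returns one row per (mapping, statistic in {EiC, ED}) with columns
    ``mapping_id, statistic, population_mean, sample_mean, sample_sd, n,
    t, p_value`` — the machine twin of a top-k-vs-population summary table.
    Mappings with fewer than two top-k members are skipped with a warning.
    """
    rows = []
    for mapping_id, sub in scores.groupby("mapping_id", sort=True):
        ids = top_k(scores, mapping_id, k)
        top = sub[sub["antibody_id"].isin(ids)]
        if len(top) < 2:
            warnings.warn(
                f"mapping {mapping_id!r}: fewer than two top-k antibodies; skipped",
                stacklevel=2,
            )
            continue
        for statistic in ("EiC", "ED"):
            res = one_sample_t_test(
                top[statistic], sub[statistic].mean(), alternative=alternative
            )
            rows.append(
                (
                    mapping_id,
                    statistic,
                    res.population_mean,
                    res.sample_mean,
                    res.sample_sd,
                    res.n,
                    res.t_statistic,
                    res.p_value,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "mapping_id",
            "statistic",
            "population_mean",
            "sample_mean",
            "sample_sd",
            "n",
            "t",
            "p_value",
        ],
    )


def _ed_wide(scores: pd.DataFrame, ed_matrix: EDMatrix | None) -> pd.DataFrame:
    if ed_matrix is not None:
        return ed_matrix.ed
    return scores.pivot(index="antibody_id", columns="mapping_id", values="ED")


def ed_heatmap(
    scores: pd.DataFrame,
    k: int = 100,
    ed_matrix: EDMatrix | None = None,
    registry: Sequence[MappingDef] | None = None,
) -> pd.DataFrame:
    """Mean-ED heat map of the top-k antibodies of every mapping.

    Rows are evaluation mappings i, columns are selection mappings j plus a
    final "All" column; cell (i, j) averages the ED on mapping i of the
    top-k antibodies of mapping j, skipping antibodies untested on i.  The
    "All" column holds the population ED mean of each row and does not
    depend on k.  Passing the EDMatrix lets selected antibodies be evaluated
    also on mappings where they were unscorable; the registry fixes row and
    column order.
    """
    wide = _ed_wide(scores, ed_matrix)
    if registry is not None:
        order = [m.mapping_id for m in registry if m.mapping_id in wide.columns]
        wide = wide.loc[:, order]
    mapping_ids = [m for m in wide.columns if m in set(scores["mapping_id"])]
    cols = {}
    for j in mapping_ids:
        selected = top_k(scores, j, k)
        cols[j] = wide.reindex(selected).mean(axis=0)
    cols[ALL_COLUMN] = wide.mean(axis=0)
    heat = pd.DataFrame(cols)
    heat = heat.loc[wide.columns, :]  # row order = mapping order
    heat.index.name = "mapping_id"
    return heat


def write_validation(validation: pd.DataFrame, path: str | Path) -> None:
    validation.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_heatmap(heat: pd.DataFrame, path: str | Path) -> None:
    heat.to_csv(path, sep="\t", float_format="%.6g")


def render_heatmap(heat: pd.DataFrame, path: str | Path) -> None:
    """Render the heat map to an image (light -> dark blue scale)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(0.35 * len(heat.columns) + 2, 0.3 * len(heat) + 2)
    )
    im = ax.imshow(heat.to_numpy(dtype=float), cmap="Blues", aspect="auto")
    ax.set_xticks(range(len(heat.columns)), heat.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(heat.index)), heat.index, fontsize=6)
    ax.set_xlabel("selection mapping (top-k)")
    ax.set_ylabel("evaluation mapping")
    fig.colorbar(im, ax=ax, label="mean ED")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
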