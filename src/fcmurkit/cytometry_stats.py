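"""Flow-cytometry MFI-index statistics.

Surface staining of receptor transductants is quantified with a
background-corrected, expression-normalised index computed from an equal
mixture of GFP-positive transduced cells and GFP-negative control cells:

    MFI index = (PE_t - PE_c) / (GFP_t - GFP_c)

where the subscripts mark the transductant and control populations.
Subtracting the control PE removes staining background; dividing by the GFP
difference normalises to transgene expression.  Replicate indices are
summarised as mean ± SD and each construct is compared with wild type by a
pooled-variance two-sided Student's t test with significance tiers at
0.05 / 0.01 / 0.001.

Inputs are compensated summaries or event tables with population labels;
gating itself is upstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .melt_analysis import TTestResult

TIER_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


class UndefinedIndexError(ValueError):
    """GFP difference is not positive — the GFP gate failed."""


@dataclass(frozen=True)
class MFIRecord:
    """Per-replicate channel summaries for one transductant/control mixture."""

    construct: str
    probe: str
    pe_transductant: float
    pe_control: float
    gfp_transductant: float
    gfp_control: float
    replicate: int = 1


def compute_mfi(
    events: pd.DataFrame,
    channel: str,
    population: str,
    statistic: str = "arithmetic",
) -> float:
    """MFI of one channel in one labelled population.

    ``statistic`` is ``arithmetic`` (default) or ``geometric`` — cytometry
    software varies, so both are offered.
    """
    values = events.loc[events["population"] == population, channel].to_numpy(float)
    if values.size == 0:
        raise ValueError(f"population {population!r} is empty")
    if statistic == "arithmetic":
        return float(values.mean())
    if statistic == "geometric":
        if np.any(values <= 0):
            raise ValueError("geometric mean requires positive values")
        return float(np.exp(np.log(values).mean()))
    raise ValueError(f"unknown statistic {statistic!r}")


def mfi_index(rec: MFIRecord) -> float:
    """The background-corrected, expression-normalised staining index."""
    gfp_diff = rec.gfp_transductant - rec.gfp_control
    if gfp_diff <= 0:
        raise UndefinedIndexError(
            f"{rec.construct}/{rec.probe}: GFP(transductant) - GFP(control) = "
            f"{gfp_diff:g} <= 0; index undefined"
        )
    return (rec.pe_transductant - rec.pe_control) / gfp_diff


def record_from_events(
    events: pd.DataFrame,
    construct: str = "",
    probe: str = "",
    replicate: int = 1,
    statistic: str = "arithmetic",
    transductant_label: str = "transductant",
    control_label: str = "control",
) -> MFIRecord:
    """Collapse an event table (columns PE, GFP, population) to an MFIRecord."""
    return MFIRecord(
        construct=construct,
        probe=probe,
        replicate=replicate,
        pe_transductant=compute_mfi(events, "PE", transductant_label, statistic),
        pe_control=compute_mfi(events, "PE", control_label, statistic),
        gfp_transductant=compute_mfi(events, "GFP", transductant_label, statistic),
        gfp_control=compute_mfi(events, "GFP", control_label, statistic),
    )


@dataclass(frozen=True)
class ConstructSummary:
    mean: float
    sd: float
    n: int
    sd_defined: bool  # False when n = 1 (SD reported as 0 but meaningless)


def summarize_construct(indices: Sequence[float]) -> ConstructSummary:
    """Sample mean and SD (n-1 denominator) of replicate indices."""
    arr = np.asarray(indices, dtype=float)
    if arr.size < 1:
        raise ValueError("need at least one replicate")
    if arr.size == 1:
        return ConstructSummary(mean=float(arr[0]), sd=0.0, n=1, sd_defined=False)
    return ConstructSummary(
        mean=float(arr.mean()), sd=float(arr.std(ddof=1)), n=int(arr.size),
        sd_defined=True,
    )


def significance_tier(p: float) -> str:
    for threshold, tier in TIER_THRESHOLDS:
        if p < threshold:
            return tier
    return "ns"


def compare_to_wt(
    construct_indices: Sequence[float],
    wt_indices: Sequence[float],
    equal_var: bool = True,
) -> tuple[TTestResult, str]:
    """Two-sided Student's t test of a construct's replicate indices against
    wild type, with the significance tier (ns / * / ** / ***)."""
    a = np.asarray(construct_indices, dtype=float)
    b = np.asarray(wt_indices, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need n >= 2 replicates per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        p = 1.0 if a.mean() == b.mean() else 0.0
        res = TTestResult(
            t=0.0 if p == 1.0 else float("inf"),
            df=a.size + b.size - 2, p=p, degenerate=True,
        )
    else:
        r = stats.ttest_ind(a, b, equal_var=equal_var)
        res = TTestResult(t=float(r.statistic), df=float(r.df), p=float(r.pvalue))
    return res, significance_tier(res.p)


def summarize_panel(
    records: pd.DataFrame, wt_label: str, equal_var: bool = True
) -> pd.DataFrame:
    """Panel summary in the mutant-versus-WT layout.

    ``records`` has columns construct, probe, replicate, PE_t, PE_c, GFP_t,
    GFP_c.  Returns one row per (construct, probe) with mean, SD, n, p
    versus wild type and the significance tier (WT rows get p = 1, ns).
    """
    required = {"construct", "probe", "replicate", "PE_t", "PE_c", "GFP_t", "GFP_c"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns {sorted(missing)}")
    idx = records.apply(
        lambda row: mfi_index(MFIRecord(
            construct=row["construct"], probe=row["probe"],
            replicate=int(row["replicate"]),
            pe_transductant=row["PE_t"], pe_control=row["PE_c"],
            gfp_transductant=row["GFP_t"], gfp_control=row["GFP_c"],
        )),
        axis=1,
    )
    df = records.assign(index_value=idx)
    rows = []
    for (construct, probe), grp in df.groupby(["construct", "probe"], sort=False):
        values = grp["index_value"].to_numpy(float)
        summary = summarize_construct(values)
        wt = df[(df["construct"] == wt_label) & (df["probe"] == probe)]
        if construct == wt_label or wt.empty:
            p, tier = (1.0, "ns") if construct == wt_label else (float("nan"), "ns")
        else:
            res, tier = compare_to_wt(values, wt["index_value"].to_numpy(float),
                                      equal_var=equal_var)
            p = res.p
        rows.append({
            "construct": construct, "probe": probe,
            "mean_index": summary.mean, "sd_index": summary.sd, "n": summary.n,
            "p_vs_wt": p, "tier": tier,
        })
    return pd.DataFrame(rows)
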