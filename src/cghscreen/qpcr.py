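"""Relative copy-number estimation from TaqMan qPCR and validation tests.

The quantification follows the comparative-CT (ΔΔCT) rule under a
single-efficiency model (one cycle per halving of template):

    ΔCT(sample)  = mean CT_target − mean CT_internal_control
    ΔΔCT(sample) = ΔCT(sample) − ΔCT(calibrator)
    copy number  = 2 · 2^(−ΔΔCT)

so ΔΔCT = 0 maps to the diploid two copies and each extra cycle halves
the estimate.  The calibrator is, by default, the control group's median
ΔCT within each brain region ("control-median") — a robust stand-in for
a known-diploid reference sample.

Three validation statistics mirror a case-control dosage study design:

* ``pair_anova`` — two-way fixed-effects ANOVA (disease × sample pair) on
  replicate-level copy numbers, for loci assayed in matched pairs;
* ``group_compare`` — chi-square on integer-rounded copy-number classes
  plus a Mann–Whitney U test on the raw values, for group-level screens;
* ``region_ratio_test`` — per-pair case/control dosage ratios compared
  between two brain regions by two-way ANOVA (region × pair), asking
  whether an aberration is regional or shared (hence likely of early
  developmental or germline origin).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)

INTERNAL_CONTROL = "internal_control"

PLATE_COLUMNS = ["sample", "group", "region", "assay", "replicate", "ct"]


def _check_plate(plate: pd.DataFrame) -> pd.DataFrame:
    missing = set(PLATE_COLUMNS) - set(plate.columns)
    if missing:
        raise ValueError(f"qPCR plate missing columns: {sorted(missing)}")
    return plate


def delta_delta_ct(
    plate: pd.DataFrame,
    target: str,
    calibrator_rule: str = "control-median",
    internal_control: str = INTERNAL_CONTROL,
) -> pd.DataFrame:
    """Per-(sample, region) ΔCT and ΔΔCT for one target assay.

    Samples lacking internal-control wells (or target wells) in a region
    are excluded with a warning.  Returns columns
    ``sample, group, region, dct, ddct``.
    """
    plate = _check_plate(plate)
    sub = plate[plate["assay"].isin([target, internal_control])]
    rows = []
    for (sample, region), grp in sub.groupby(["sample", "region"], sort=False):
        t_ct = grp.loc[grp["assay"] == target, "ct"]
        c_ct = grp.loc[grp["assay"] == internal_control, "ct"]
        if len(t_ct) == 0:
            continue  # target simply not assayed for this sample/region
        if len(c_ct) == 0:
            logger.warning(
                "sample %s region %s: no internal-control wells; excluded",
                sample,
                region,
            )
            continue
        rows.append(
            {
                "sample": sample,
                "group": grp["group"].iloc[0],
                "region": region,
                "dct": float(t_ct.mean() - c_ct.mean()),
            }
        )
    out = pd.DataFrame(rows, columns=["sample", "group", "region", "dct"])
    if len(out) == 0:
        raise ValueError(f"no samples with both {target!r} and internal control")
    if calibrator_rule != "control-median":
        raise ValueError(f"unknown calibrator rule: {calibrator_rule!r}")
    # calibrator: control-group median ΔCT, within each region
    cal = (
        out[out["group"] == "control"]
        .groupby("region")["dct"]
        .median()
        .rename("calibrator_dct")
    )
    if len(cal) == 0:
        raise ValueError("calibrator requires at least one control-group sample")
    out = out.merge(cal, on="region", how="left")
    out["ddct"] = out["dct"] - out["calibrator_dct"]
    return out.drop(columns="calibrator_dct")


def copy_number(ddct):
    """Copy number from ΔΔCT: 2 · 2^(−ΔΔCT).  Strictly decreasing;
    ΔΔCT = 0 gives exactly 2."""
    out = 2.0 * 2.0 ** (-np.asarray(ddct, dtype=float))
    return float(out) if np.ndim(ddct) == 0 else out


def replicate_copy_numbers(
    plate: pd.DataFrame,
    target: str,
    calibrator_rule: str = "control-median",
    internal_control: str = INTERNAL_CONTROL,
) -> pd.DataFrame:
    """Replicate-level copy numbers (technical deviations retained).

    Replicate r of the target is paired with replicate r of the internal
    control on the same (sample, region); the calibrator ΔCT comes from
    the sample-level estimates of :func:`delta_delta_ct`.  Returns columns
    ``sample, group, region, replicate, cn``.
    """
    plate = _check_plate(plate)
    sample_level = delta_delta_ct(plate, target, calibrator_rule, internal_control)
    cal_by_region = (
        (sample_level["dct"] - sample_level["ddct"])
        .groupby(sample_level["region"])
        .first()
    )
    t = plate[plate["assay"] == target]
    c = plate[plate["assay"] == internal_control]
    merged = t.merge(
        c,
        on=["sample", "group", "region", "replicate"],
        suffixes=("_t", "_c"),
    )
    dropped = len(t) - len(merged)
    if dropped:
        logger.warning(
            "%d target wells had no matching internal-control replicate", dropped
        )
    merged["ddct"] = (
        merged["ct_t"] - merged["ct_c"] - merged["region"].map(cal_by_region)
    )
    merged["cn"] = copy_number(merged["ddct"].to_numpy())
    return merged[["sample", "group", "region", "replicate", "cn"]]


def sample_copy_numbers(
    plate: pd.DataFrame,
    target: str,
    calibrator_rule: str = "control-median",
    internal_control: str = INTERNAL_CONTROL,
) -> pd.DataFrame:
    """Per-sample copy-number estimates: columns
    ``sample, group, region, ddct, cn``."""
    out = delta_delta_ct(plate, target, calibrator_rule, internal_control)
    out["cn"] = copy_number(out["ddct"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# Validation statistics


def pair_anova(cn: pd.DataFrame) -> pd.DataFrame:
    """Two-way fixed-effects ANOVA on replicate-level copy numbers.

    ``cn`` needs columns ``pair``, ``disease`` (two levels) and ``cn``
    (one row per technical replicate).  Returns a table with one row per
    factor carrying F and p (type-II sums of squares).  If the response is
    constant the F ratio is 0/0; by convention p = 1 is reported.
    """
    for col in ("pair", "disease", "cn"):
        if col not in cn.columns:
            raise ValueError(f"pair_anova input missing column {col!r}")
    if cn["pair"].nunique() < 2:
        raise ValueError("pair_anova requires >= 2 pairs")
    if cn["disease"].nunique() != 2:
        raise ValueError("pair_anova requires exactly 2 disease levels")
    counts = cn.groupby(["pair", "disease"], observed=True).size()
    full = pd.MultiIndex.from_product(
        [cn["pair"].unique(), cn["disease"].unique()], names=["pair", "disease"]
    )
    empty = full.difference(counts.index)
    if len(empty) > 0:
        raise ValueError(f"empty cell (pair, disease) = {tuple(empty[0])}")
    if (counts < 2).any():
        raise ValueError("pair_anova requires >= 2 replicates per cell")
    if np.allclose(cn["cn"].to_numpy(), cn["cn"].iloc[0]):
        return pd.DataFrame(
            {"F": [0.0, 0.0], "p": [1.0, 1.0]},
            index=pd.Index(["disease", "pair"], name="factor"),
        )
    model = smf.ols("cn ~ C(disease) + C(pair)", data=cn).fit()
    table = sm.stats.anova_lm(model, typ=2)
    return pd.DataFrame(
        {
            "F": [table.loc["C(disease)", "F"], table.loc["C(pair)", "F"]],
            "p": [table.loc["C(disease)", "PR(>F)"], table.loc["C(pair)", "PR(>F)"]],
        },
        index=pd.Index(["disease", "pair"], name="factor"),
    )


def round_copy_number(cn) -> np.ndarray:
    """Integer copy-number class, rounding half away from zero
    (cn is positive, so 1.5 -> 2, 2.5 -> 3)."""
    return np.floor(np.asarray(cn, dtype=float) + 0.5).astype(int)


def _pool_rare_categories(table: pd.DataFrame) -> pd.DataFrame:
    """Merge adjacent integer-cn categories until every expected cell
    count is >= 1 (or only two categories remain).  The sparsest category
    is folded into its nearest neighbour; deterministic."""
    while len(table) > 2:
        grand = table.to_numpy().sum()
        expected = (
            np.outer(table.sum(axis=1), table.sum(axis=0)) / grand
        )
        if expected.min() >= 1.0:
            break
        row = int(np.argmin(table.sum(axis=1).to_numpy()))
        neighbour = row - 1 if row > 0 else row + 1
        idx = list(table.index)
        table.iloc[neighbour] += table.iloc[row]
        table = table.drop(index=idx[row])
    return table


def group_compare(cn: pd.DataFrame) -> dict:
    """Group-level dosage comparison: chi-square on integer copy-number
    classes and Mann–Whitney U on the raw values.

    ``cn`` needs columns ``group`` (two levels) and ``cn`` (one row per
    subject).  Returns chi2_p, mwu_p, the pooled contingency table and a
    ``chi2_degenerate`` flag (set when a single copy-number class remains,
    leaving the chi-square undefined).
    """
    for col in ("group", "cn"):
        if col not in cn.columns:
            raise ValueError(f"group_compare input missing column {col!r}")
    groups = sorted(cn["group"].unique())
    if len(groups) != 2:
        raise ValueError("group_compare requires exactly 2 groups")
    a = cn.loc[cn["group"] == groups[0], "cn"].to_numpy(dtype=float)
    b = cn.loc[cn["group"] == groups[1], "cn"].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("group_compare requires >= 2 subjects per group")

    classes = pd.Series(round_copy_number(cn["cn"]), name="cn_class")
    table = pd.crosstab(classes, cn["group"].reset_index(drop=True)).sort_index()
    table = _pool_rare_categories(table)
    if len(table) < 2:
        chi2_p = float("nan")
        degenerate = True
    else:
        chi2_p = float(stats.chi2_contingency(table.to_numpy(), correction=False)[1])
        degenerate = False
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        mwu_p = 1.0  # identical constant samples: no evidence either way
    else:
        mwu_p = float(
            stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        )
    return {
        "chi2_p": chi2_p,
        "mwu_p": mwu_p,
        "contingency": table,
        "chi2_degenerate": degenerate,
        "rounding": "half away from zero",
    }


def region_ratio_test(cn: pd.DataFrame, pairing: list[tuple[str, str]]) -> dict:
    """Case/control dosage ratios per pair and region, compared between
    regions by two-way ANOVA (region × pair) on replicate-level ratios.

    ``cn`` is replicate-level (from :func:`replicate_copy_numbers`) with
    both regions measured; replicate r of the case is ratioed against
    replicate r of its matched control.  Pairs missing a region are
    skipped with a warning.  Returns the per-pair ratio table
    (``pair, region, replicate, ratio``), a per-(pair, region) summary of
    mean ratios, and the ANOVA table.
    """
    rows = []
    regions = sorted(cn["region"].unique())
    for (case_id, ctrl_id) in pairing:
        for region in regions:
            c_rep = cn[(cn["sample"] == case_id) & (cn["region"] == region)]
            k_rep = cn[(cn["sample"] == ctrl_id) & (cn["region"] == region)]
            merged = c_rep.merge(k_rep, on="replicate", suffixes=("_case", "_ctrl"))
            if len(merged) == 0:
                logger.warning(
                    "pair (%s, %s) missing region %s; skipped", case_id, ctrl_id, region
                )
                continue
            for _, r in merged.iterrows():
                rows.append(
                    {
                        "pair": f"{case_id}:{ctrl_id}",
                        "region": region,
                        "replicate": int(r["replicate"]),
                        "ratio": float(r["cn_case"] / r["cn_ctrl"]),
                    }
                )
    ratios = pd.DataFrame(rows, columns=["pair", "region", "replicate", "ratio"])
    if len(ratios) == 0:
        raise ValueError("no pair has both regions measured")
    summary = (
        ratios.groupby(["pair", "region"], observed=True)["ratio"]
        .mean()
        .reset_index()
    )
    if ratios["region"].nunique() < 2 or ratios["pair"].nunique() < 2:
        anova = None
    elif np.allclose(ratios["ratio"], ratios["ratio"].iloc[0]):
        anova = pd.DataFrame(
            {"F": [0.0, 0.0], "p": [1.0, 1.0]},
            index=pd.Index(["region", "pair"], name="factor"),
        )
    else:
        model = smf.ols("ratio ~ C(region) + C(pair)", data=ratios).fit()
        table = sm.stats.anova_lm(model, typ=2)
        anova = pd.DataFrame(
            {
                "F": [table.loc["C(region)", "F"], table.loc["C(pair)", "F"]],
                "p": [table.loc["C(region)", "PR(>F)"], table.loc["C(pair)", "PR(>F)"]],
            },
            index=pd.Index(["region", "pair"], name="factor"),
        )
    return {"ratios": ratios, "summary": summary, "anova": anova}
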