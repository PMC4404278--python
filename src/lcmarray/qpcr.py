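"""Relative qPCR quantification (delta-delta-Ct) and two-way ANOVA.

Target Ct values are normalized per sample to a reference transcript
(ribosomal protein L32 in the validation experiments), then to the mean
delta-Ct of a calibrator group (GF within the same tissue/fraction by
default), and expressed as fold change 2^(-ddCt) assuming amplification
efficiency 2.  Group differences are tested on the delta-Ct (log) scale
with a classical two-way fixed-effects ANOVA (status x fraction) with
interaction, using Type-II sums of squares to tolerate mild imbalance.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.formula.api import ols

from .containers import ValidationError

logger = logging.getLogger(__name__)

__all__ = ["read_ct_tsv", "write_ct_tsv", "delta_delta_ct", "two_way_anova"]

CT_COLUMNS = ["gene", "sample", "tissue", "fraction", "status", "ct"]


def read_ct_tsv(path) -> pd.DataFrame:
    """Read a Ct table (TSV, columns gene/sample/tissue/fraction/status/ct).

    'nd' (not detectable) wells become missing values; a count is logged.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: Ct table missing columns {missing}")
    nd = df["ct"].str.strip().str.lower().isin({"nd", "na", ""})
    if nd.any():
        logger.info("%s: %d 'nd' wells treated as missing", path, int(nd.sum()))
    df.loc[nd, "ct"] = np.nan
    df["ct"] = df["ct"].astype(float)
    if (df["ct"].dropna() <= 0).any():
        raise ValidationError(f"{path}: non-positive Ct value")
    return df


def write_ct_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def delta_delta_ct(
    ct_table: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    calibrator_status: str = "GF",
    within: tuple = ("tissue", "fraction"),
) -> pd.DataFrame:
    """Per-sample relative expression of ``target_gene`` by delta-delta-Ct.

    dCt = Ct_target - Ct_reference per sample; ddCt subtracts the mean dCt
    of the calibrator group (``calibrator_status`` within the same levels of
    ``within``); relative expression is 2^(-ddCt).  Samples whose target Ct
    is missing ('nd') are dropped with a log message; a missing reference
    well is an error naming the sample.
    """
    t = ct_table[ct_table["gene"] == target_gene].set_index("sample")
    r = ct_table[ct_table["gene"] == reference_gene].set_index("sample")
    if t.empty:
        raise ValidationError(f"no wells for target gene {target_gene!r}")
    missing_ref = [s for s in t.index if s not in r.index or pd.isna(r.loc[s, "ct"])]
    if missing_ref:
        raise ValidationError(
            f"missing reference ({reference_gene}) well for sample(s): {missing_ref[:5]}"
        )
    nd = t["ct"].isna()
    if nd.any():
        logger.info(
            "target %s: dropping %d 'nd' sample(s): %s",
            target_gene, int(nd.sum()), list(t.index[nd])[:5],
        )
        t = t[~nd]
    out = t[["tissue", "fraction", "status"]].copy()
    out["dct"] = t["ct"] - r.loc[t.index, "ct"]

    group_cols = list(within)
    ddct = np.empty(len(out))
    for key, sub in out.groupby(group_cols, sort=False):
        cal = sub[sub["status"] == calibrator_status]
        if cal.empty:
            raise ValidationError(
                f"calibrator group {calibrator_status!r} empty for {dict(zip(group_cols, key if isinstance(key, tuple) else (key,)))}"
            )
        baseline = cal["dct"].mean()
        ddct[out.index.get_indexer(sub.index)] = sub["dct"] - baseline
    out["ddct"] = ddct
    out["fold"] = 2.0 ** (-out["ddct"])
    return out.reset_index()


def two_way_anova(
    values: pd.DataFrame,
    response: str = "dct",
    factor_a: str = "status",
    factor_b: str = "fraction",
) -> pd.DataFrame:
    """Two-way fixed-effects ANOVA with interaction (Type-II SS).

    Returns a table indexed by effect (factor_a, factor_b, interaction,
    residual) with sum_sq, df, F and p columns.  Requires >=2 levels per
    factor and >=2 observations per cell.
    """
    df = values[[response, factor_a, factor_b]].dropna().copy()
    for factor in (factor_a, factor_b):
        if df[factor].nunique() < 2:
            raise ValidationError(f"factor {factor!r} needs >=2 levels")
    cell_counts = df.groupby([factor_a, factor_b], observed=True).size()
    expected_cells = df[factor_a].nunique() * df[factor_b].nunique()
    if len(cell_counts) < expected_cells or (cell_counts < 2).any():
        raise ValidationError("every factor-level cell needs >=2 observations")
    model = ols(
        f"Q('{response}') ~ C(Q('{factor_a}')) * C(Q('{factor_b}'))", data=df
    ).fit()
    table = sm.stats.anova_lm(model, typ=2)
    rename = {}
    for idx in table.index:
        if factor_a in idx and factor_b in idx:
            rename[idx] = "interaction"
        elif factor_a in idx:
            rename[idx] = factor_a
        elif factor_b in idx:
            rename[idx] = factor_b
        else:
            rename[idx] = "residual"
    table = table.rename(index=rename)
    table = table.rename(columns={"PR(>F)": "p"})
    return table
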