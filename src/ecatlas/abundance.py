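"""Per-patient cluster composition and paired tumor vs peri-tumoral testing.

Composition is the fraction of each patient-condition sample's cells falling
in each cluster (fractions sum to 1 within a sample; clusters absent from a
sample get 0). Condition differences are tested per cluster with a paired
two-tailed t-test over patients contributing both conditions; related
clusters (e.g. the angiogenic or capillary groups) can be pooled by summing
their fractions first. No multiple-testing correction is applied by default
(per-subcluster p-values are reported); a BH option is available.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def composition(
    labels: pd.Series | np.ndarray,
    patient: pd.Series | np.ndarray,
    condition: pd.Series | np.ndarray,
) -> pd.DataFrame:
    """Long-format table (patient, condition, cluster, fraction)."""
    df = pd.DataFrame(
        {
            "cluster": np.asarray(labels),
            "patient": np.asarray(patient),
            "condition": np.asarray(condition),
        }
    )
    clusters = sorted(df["cluster"].unique(), key=str)
    out = []
    for (pat, cond), grp in df.groupby(["patient", "condition"]):
        if len(grp) == 0:
            warnings.warn(f"({pat}, {cond}) has 0 cells; omitted")
            continue
        frac = grp["cluster"].value_counts(normalize=True)
        for c in clusters:
            out.append(
                {
                    "patient": pat,
                    "condition": cond,
                    "cluster": c,
                    "fraction": float(frac.get(c, 0.0)),
                }
            )
    return pd.DataFrame(out)


def paired_condition_test(
    ct: pd.DataFrame,
    groups: dict[str, list] | None = None,
    conditions: tuple[str, str] = ("tumor", "peritumor"),
    bh: bool = False,
) -> pd.DataFrame:
    """Paired two-tailed t per cluster (or pooled cluster group) between
    conditions, using only patients with both conditions present.

    The t statistic is computed on per-patient fraction differences
    (first condition minus second). ``groups`` maps a group name to the
    clusters whose fractions are summed before testing.
    """
    wide = ct.pivot_table(
        index=["patient", "condition"], columns="cluster", values="fraction",
        fill_value=0.0,
    )
    if groups:
        pooled = pd.DataFrame(
            {name: wide[cols].sum(axis=1) for name, cols in groups.items()}
        )
        wide = pooled
    a, b = conditions
    pats_a = set(wide.index[wide.index.get_level_values("condition") == a].get_level_values("patient"))
    pats_b = set(wide.index[wide.index.get_level_values("condition") == b].get_level_values("patient"))
    complete = sorted(pats_a & pats_b)
    if len(complete) < 2:
        raise ValueError("need >= 2 complete patient pairs")
    A = wide.loc[[(p, a) for p in complete]].to_numpy()
    B = wide.loc[[(p, b) for p in complete]].to_numpy()
    rows = []
    for j, cl in enumerate(wide.columns):
        if np.allclose(A[:, j], B[:, j]):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(A[:, j], B[:, j])
        rows.append({"cluster_or_group": cl, "t": float(t), "p": float(p),
                     "n_pairs": len(complete)})
    out = pd.DataFrame(rows)
    if bh:
        out["adj_p"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
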