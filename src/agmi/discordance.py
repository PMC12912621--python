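"""GMI, discordance, phenotype classification and longitudinal persistence.

The glucose management indicator estimates HbA1c from CGM mean glucose,

    GMI(%) = 3.31 + 0.02392 x mean glucose [mg/dL]

and discordance is the signed gap ``HbA1c - GMI`` for a pair: positive means
the laboratory value runs above what glucose exposure predicts (a "high
glycator"). Pairs are phenotyped as positive (d >= +0.5%), negative
(d <= -0.5%) or neutral (in between); the boundary values +/-0.5 belong to
the positive/negative groups. Baseline phenotype is the group at a
subject's first pair; persistence and reclassification are measured against
it and between consecutive pairs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import KruskalWallisResult, kruskal_wallis

GMI_INTERCEPT = 3.31
GMI_SLOPE = 0.02392

#: phenotype threshold, % HbA1c
DISCORDANCE_THRESHOLD = 0.5

GROUPS = ("positive", "neutral", "negative")


def gmi_from_mean(mean_glucose_mgdl):
    """GMI (%) from window mean glucose (mg/dL); strictly increasing affine."""
    x = np.asarray(mean_glucose_mgdl, dtype=float)
    if np.any(x <= 0) or np.any(x >= 1000):
        raise ValueError("mean glucose must lie in (0, 1000) mg/dL")
    out = GMI_INTERCEPT + GMI_SLOPE * x
    return out.item() if np.isscalar(mean_glucose_mgdl) else out


def discordance(hba1c_percent, gmi_percent):
    """Signed discordance HbA1c - GMI (%); positive = HbA1c above GMI."""
    return np.subtract(hba1c_percent, gmi_percent)


def classify(discordance_percent, threshold: float = DISCORDANCE_THRESHOLD):
    """Phenotype label(s) for discordance value(s).

    positive iff d >= threshold, negative iff d <= -threshold, else neutral.
    """
    d = np.asarray(discordance_percent, dtype=float)
    out = np.where(d >= threshold, "positive",
                   np.where(d <= -threshold, "negative", "neutral"))
    return out.item() if np.isscalar(discordance_percent) else out


def add_discordance(pairs: pd.DataFrame,
                    threshold: float = DISCORDANCE_THRESHOLD) -> pd.DataFrame:
    """Append ``gmi``, ``discordance`` and ``group`` columns to a pair table."""
    out = pairs.copy()
    if out.empty:
        out["gmi"] = out["discordance"] = out["group"] = pd.Series(dtype=object)
        return out
    out["gmi"] = gmi_from_mean(out["mean_glucose"].to_numpy())
    out["discordance"] = discordance(out["hba1c"].to_numpy(), out["gmi"].to_numpy())
    out["group"] = classify(out["discordance"].to_numpy(), threshold)
    return out


def prevalence(pairs: pd.DataFrame, threshold: float) -> float:
    """Fraction of pairs with absolute discordance at or above ``threshold``."""
    if len(pairs) == 0:
        raise ValueError("prevalence requires a non-empty pair table")
    return float((pairs["discordance"].abs() >= threshold).mean())


def baseline_groups(pairs: pd.DataFrame) -> pd.Series:
    """Baseline (pair 0) phenotype per subject."""
    base = pairs.loc[pairs["pair_index"] == 0]
    return base.set_index("subject_id")["group"]


def transition_table(pairs: pd.DataFrame, target_pair_index: int) -> pd.DataFrame:
    """Baseline-group -> group-at-target counts.

    Rows are baseline groups, columns target groups; only subjects that
    actually have a pair at ``target_pair_index`` contribute, so each row
    total equals the baseline count restricted to those subjects.
    """
    if target_pair_index < 1:
        raise ValueError("target_pair_index must be >= 1")
    base = baseline_groups(pairs)
    target = (pairs.loc[pairs["pair_index"] == target_pair_index]
              .set_index("subject_id")["group"])
    joined = pd.DataFrame({"from": base, "to": target}).dropna()
    table = pd.crosstab(joined["from"], joined["to"])
    return table.reindex(index=GROUPS, columns=GROUPS, fill_value=0)


def persistence_rate(table: pd.DataFrame, group: str) -> float:
    """Diagonal fraction of a transition-table row (stay-in-group rate)."""
    row_total = int(table.loc[group].sum())
    if row_total == 0:
        raise ValueError(f"no subjects in baseline group {group!r} at the target pair")
    return float(table.loc[group, group]) / row_total


def reclassification_rate(pairs: pd.DataFrame,
                          origins=("positive", "negative")) -> float:
    """Fraction of consecutive-pair transitions that change group label.

    Only transitions whose origin pair carries a label in ``origins``
    (default: the positive and negative phenotypes) enter the denominator;
    pass all three labels to count every transition.
    """
    srt = pairs.sort_values(["subject_id", "pair_index"], kind="stable")
    nxt = srt.groupby("subject_id")["group"].shift(-1)
    mask = nxt.notna() & srt["group"].isin(origins)
    if not mask.any():
        raise ValueError("no qualifying consecutive transitions")
    return float((srt.loc[mask, "group"] != nxt[mask]).mean())


def interval_discordance_correlation(pairs: pd.DataFrame) -> tuple[float, float]:
    """Pearson r (and two-sided p) between follow-up interval and |discordance|.

    Uses every follow-up pair (pair_index >= 1): x = days since the
    subject's baseline pair, y = absolute discordance. The p-value comes
    from the t distribution with n - 2 degrees of freedom.
    """
    fu = pairs.loc[pairs["pair_index"] >= 1]
    if len(fu) < 3:
        raise ValueError("need at least 3 follow-up pairs")
    x = fu["days_since_baseline"].to_numpy(dtype=float)
    y = fu["discordance"].abs().to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("degenerate variance: correlation undefined")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def groupwise_kruskal_wallis(pairs: pd.DataFrame, pair_index: int) -> KruskalWallisResult:
    """Compare discordance across baseline phenotypes at one pair index."""
    base = baseline_groups(pairs)
    at = pairs.loc[pairs["pair_index"] == pair_index].set_index("subject_id")
    groups = []
    for g in GROUPS:
        members = base.index[base == g]
        vals = at.loc[at.index.intersection(members), "discordance"].to_numpy()
        if len(vals):
            groups.append(vals)
    return kruskal_wallis(groups)


def posthoc_pairwise(pairs: pd.DataFrame, pair_index: int) -> pd.DataFrame:
    """Bonferroni-corrected pairwise rank-sum tests between baseline groups."""
    base = baseline_groups(pairs)
    at = pairs.loc[pairs["pair_index"] == pair_index].set_index("subject_id")
    samples = {}
    for g in GROUPS:
        members = base.index[base == g]
        vals = at.loc[at.index.intersection(members), "discordance"].to_numpy()
        if len(vals):
            samples[g] = vals
    names = list(samples)
    rows = []
    n_tests = len(names) * (len(names) - 1) // 2
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            stat, p = sps.mannwhitneyu(samples[a], samples[b], alternative="two-sided")
            rows.append({"group_a": a, "group_b": b, "u": float(stat),
                         "p_raw": float(p), "p_bonferroni": min(1.0, float(p) * n_tests)})
    return pd.DataFrame(rows)


def sankey_table(pairs: pd.DataFrame, max_pair_index: int = 2) -> pd.DataFrame:
    """Long-format baseline->target counts for Sankey-style plotting."""
    rows = []
    for idx in range(1, max_pair_index + 1):
        tab = transition_table(pairs, idx)
        for frm in GROUPS:
            for to in GROUPS:
                rows.append({"pair_index": idx, "from_group": frm, "to_group": to,
                             "count": int(tab.loc[frm, to])})
    return pd.DataFrame(rows)
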