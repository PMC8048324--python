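"""Score-trajectory stratification and the univariate statistical battery.

A patient contributes a pre- and a post-treatment sample; projecting both
onto the OPLS-DA predictive score t[1] gives a *trajectory*.  After
orienting the axis so the post-treatment class lies at positive t[1],
patients are stratified by which samples cross the class boundary (t[1]=0):

* ``Red``   - the post sample sits on the negative (pre) side: the patient
  barely moved; a weak metabolic response.
* ``Green`` - the pre sample already sits on the positive (post) side (and
  the patient is not Red): a post-like baseline.  Red takes precedence.
* ``Grey``  - everyone else: the non-mixing, full-response pattern.

The univariate battery applies Wilcoxon signed-rank (WSR) tests to paired
pre/post integrals, Mann-Whitney U (MWU) to between-group contrasts,
Kruskal-Wallis (KWA) across the three strata, and Spearman rank
correlations (SRC) between metabolite changes and clinical response, with
the between-group effect size reported as the median ratio
``100 - (lower median) / (higher median) * 100``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

STRATA = ("Grey", "Red", "Green")

#: Expected mapping between planted subgroups and recovered strata.
SUBGROUP_TO_STRATUM = {"full": "Grey", "weak_A": "Red", "weak_B": "Green"}


@dataclass
class PatientTrajectory:
    patient_id: str
    t_pre: float
    t_post: float
    stratum: str

    @property
    def distance(self) -> float:
        return abs(self.t_post - self.t_pre)

    @property
    def direction_correct(self) -> bool:
        """True when the trajectory runs pre -> post left to right."""
        return self.t_post > self.t_pre


def orient_scores(scores: pd.Series, timepoints: pd.Series) -> pd.Series:
    """Flip score signs if needed so the post class mean is positive."""
    post_mean = scores[timepoints == "post"].mean()
    return -scores if post_mean < 0 else scores


def detect_mixing(scores: pd.Series, timepoints: pd.Series,
                  patients: pd.Series) -> pd.DataFrame:
    """Assign each paired patient a stratum from its t[1] trajectory.

    Parameters
    ----------
    scores, timepoints, patients
        Aligned per-sample series: t[1] score, ``"pre"``/``"post"`` label
        and patient id.  Orientation is normalised internally.

    Returns
    -------
    DataFrame indexed by patient id with ``t_pre``, ``t_post``,
    ``distance``, ``direction_correct`` and ``stratum`` columns.  Patients
    missing a timepoint are excluded and listed in ``df.attrs["excluded"]``.
    """
    scores = orient_scores(pd.Series(np.asarray(scores, dtype=float)),
                           pd.Series(np.asarray(timepoints)))
    timepoints = pd.Series(np.asarray(timepoints))
    patients = pd.Series(np.asarray(patients))
    rows, excluded = [], []
    for pid, idx in patients.groupby(patients).groups.items():
        tp = timepoints.loc[idx]
        pre_idx = idx[tp == "pre"]
        post_idx = idx[tp == "post"]
        if len(pre_idx) != 1 or len(post_idx) != 1:
            excluded.append(pid)
            continue
        t_pre = float(scores.loc[pre_idx[0]])
        t_post = float(scores.loc[post_idx[0]])
        if t_post < 0:
            stratum = "Red"
        elif t_pre > 0:
            stratum = "Green"
        else:
            stratum = "Grey"
        rows.append({
            "patient_id": pid, "t_pre": t_pre, "t_post": t_post,
            "distance": abs(t_post - t_pre),
            "direction_correct": t_post > t_pre,
            "stratum": stratum,
        })
    df = pd.DataFrame(rows,
                      columns=["patient_id", "t_pre", "t_post", "distance",
                               "direction_correct", "stratum"])
    df = df.set_index("patient_id") if len(df) else df
    df.attrs["excluded"] = excluded
    return df


def trajectory_distance(t_pre: float, t_post: float) -> tuple[float, bool]:
    """Distance |post - pre| along t[1] and whether the direction is the
    expected pre -> post (left to right) one."""
    return abs(t_post - t_pre), t_post > t_pre


def median_ratio(values_a, values_b) -> float:
    """Between-group effect size: ``100 - (lower median)/(higher median)*100``.

    Defined for nonempty groups with positive medians; 0 for equal medians.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("median_ratio requires nonempty groups")
    med_a, med_b = float(np.median(a)), float(np.median(b))
    if med_a <= 0 or med_b <= 0:
        raise ValueError("median_ratio undefined for non-positive medians")
    lower, higher = min(med_a, med_b), max(med_a, med_b)
    return 100.0 - lower / higher * 100.0


def _wsr(pre: np.ndarray, post: np.ndarray) -> tuple[float, float]:
    """Wilcoxon signed-rank with zero-difference splitting; exact null for
    n <= 25 when scipy permits, normal approximation otherwise."""
    d = post - pre
    if np.all(d == 0):
        return 0.0, 1.0
    method = "exact" if len(d) <= 25 and not np.any(d == 0) else "approx"
    res = stats.wilcoxon(post, pre, zero_method="zsplit", method=method,
                         correction=(method == "approx"))
    return float(res.statistic), float(res.pvalue)


def paired_battery(
    metabolites: pd.DataFrame,
    strata: Mapping[str, str] | pd.Series | None = None,
    sex: Mapping[str, str] | pd.Series | None = None,
    metabolite_columns: Sequence[str] | None = None,
    min_group: int = 3,
) -> pd.DataFrame:
    """Run the WSR/MWU/KWA battery over timepoints, strata and sexes.

    Parameters
    ----------
    metabolites
        Table from :func:`nmrstrat.quantify.quantify_panel`: one row per
        sample with ``patient_id``/``timepoint`` columns and one column per
        metabolite integral.
    strata, sex
        Optional patient -> stratum / patient -> sex maps enabling the
        subgroup and sex-stratified comparisons.
    min_group
        Comparisons with any group smaller than this are skipped (the
        reason is recorded in the result row).

    Returns
    -------
    Long-format table of :class:`StatResult`-style rows: comparison, test,
    statistic, p-value, median-ratio effect size and group sizes.
    """
    if metabolite_columns is None:
        skip = {"patient_id", "timepoint", "complete"}
        metabolite_columns = [c for c in metabolites.columns
                              if c not in skip and metabolites[c].dtype.kind == "f"]
    wide = metabolites.pivot_table(index="patient_id", columns="timepoint",
                                   values=list(metabolite_columns), observed=True)
    results = []

    def _pairs(patient_ids, col):
        sub = wide.loc[list(patient_ids), col].dropna()
        return sub["pre"].to_numpy(), sub["post"].to_numpy(), sub.index

    def add(comparison, test, met, stat, p, effect, sizes, note=""):
        results.append({
            "comparison": comparison, "test": test, "metabolite": met,
            "statistic": stat, "p_value": p, "median_ratio_pct": effect,
            "group_sizes": sizes, "note": note,
        })

    all_patients = wide.index
    groups: dict[str, pd.Index] = {"all": all_patients}
    if strata is not None:
        strata = pd.Series(dict(strata)) if not isinstance(strata, pd.Series) else strata
        for s in STRATA:
            groups[s] = all_patients.intersection(strata[strata == s].index)
    if sex is not None:
        sex = pd.Series(dict(sex)) if not isinstance(sex, pd.Series) else sex
        for s in ("M", "F"):
            groups[s] = all_patients.intersection(sex[sex == s].index)

    for met in metabolite_columns:
        # paired pre vs post within each split
        for name, members in groups.items():
            pre, post, _ = _pairs(members, met)
            if len(pre) < min_group:
                add(f"pre_vs_post[{name}]", "WSR", met, np.nan, np.nan, np.nan,
                    (len(pre),), note=f"skipped: group < {min_group}")
                continue
            stat, p = _wsr(pre, post)
            try:
                effect = median_ratio(pre, post)
            except ValueError:
                effect = np.nan
            add(f"pre_vs_post[{name}]", "WSR", met, stat, p, effect,
                (len(pre), len(post)))
        # sex contrast at each timepoint
        if sex is not None:
            for timepoint in ("pre", "post"):
                m = wide.loc[groups.get("M", []), (met, timepoint)].dropna()
                f = wide.loc[groups.get("F", []), (met, timepoint)].dropna()
                name = f"M_vs_F[{timepoint}]"
                if len(m) < min_group or len(f) < min_group:
                    add(name, "MWU", met, np.nan, np.nan, np.nan,
                        (len(m), len(f)), note=f"skipped: group < {min_group}")
                    continue
                res = stats.mannwhitneyu(m, f, alternative="two-sided")
                try:
                    effect = median_ratio(m, f)
                except ValueError:
                    effect = np.nan
                add(name, "MWU", met, float(res.statistic), float(res.pvalue),
                    effect, (len(m), len(f)))
        # across strata: relative change and each timepoint
        if strata is not None:
            for label, extract in (
                ("rel_change", lambda pre, post: post / pre),
                ("pre", lambda pre, post: pre),
                ("post", lambda pre, post: post),
            ):
                samples, sizes = [], []
                for s in STRATA:
                    pre, post, _ = _pairs(groups[s], met)
                    with np.errstate(divide="ignore", invalid="ignore"):
                        samples.append(extract(pre, post))
                    sizes.append(len(pre))
                name = f"strata[{label}]"
                if min(sizes) < min_group:
                    add(name, "KWA", met, np.nan, np.nan, np.nan, tuple(sizes),
                        note=f"skipped: group < {min_group}")
                    continue
                if all(np.array_equal(samples[0], s) for s in samples[1:]):
                    add(name, "KWA", met, 0.0, 1.0, np.nan, tuple(sizes))
                    continue
                res = stats.kruskal(*samples)
                add(name, "KWA", met, float(res.statistic), float(res.pvalue),
                    np.nan, tuple(sizes))
    return pd.DataFrame(results)


def correlate_response(
    deltas: pd.DataFrame,
    responses: pd.DataFrame,
    splits: Mapping[str, Sequence[str]] | None = None,
    r_threshold: float = 0.3,
    p_threshold: float = 0.05,
    return_all: bool = False,
) -> pd.DataFrame:
    """Spearman correlations of metabolite changes against clinical response.

    Parameters
    ----------
    deltas
        Patients x metabolites table of pre - post differences.
    responses
        Patients x responses table (e.g. ``cT-yT``, ``cN-yN``,
        ``regression_pct``), aligned by patient index.
    splits
        Named patient subsets (e.g. ``{"all": ..., "M": ..., "Grey": ...}``);
        defaults to a single ``"all"`` split.
    r_threshold, p_threshold
        Retention filter: only rows with |R| > r_threshold and
        p < p_threshold are kept (the full table with a ``retained``
        column is returned when ``return_all``).

    The sign convention follows the delta = pre - post definition: a
    metabolite that *increases* under effective treatment yields negative
    deltas for strong responders, hence a negative R against regression.
    """
    common = deltas.index.intersection(responses.index)
    deltas = deltas.loc[common]
    responses = responses.loc[common]
    if splits is None:
        splits = {"all": list(common)}
    rows = []
    for split_name, members in splits.items():
        idx = common.intersection(pd.Index(members))
        for resp in responses.columns:
            r_vals = responses.loc[idx, resp]
            for met in deltas.columns:
                d_vals = deltas.loc[idx, met]
                ok = r_vals.notna() & d_vals.notna()
                n = int(ok.sum())
                if n < 3 or r_vals[ok].nunique() <= 1 or d_vals[ok].nunique() <= 1:
                    continue  # constant vector: correlation undefined
                rho, p = stats.spearmanr(d_vals[ok], r_vals[ok])
                rows.append({
                    "split": split_name, "metabolite": met, "response": resp,
                    "R": float(rho), "p_value": float(p), "n": n,
                    "retained": bool(abs(rho) > r_threshold and p < p_threshold),
                })
    table = pd.DataFrame(rows, columns=["split", "metabolite", "response",
                                        "R", "p_value", "n", "retained"])
    if return_all:
        return table
    return table[table["retained"]].drop(columns="retained").reset_index(drop=True)


def balanced_accuracy(truth: pd.Series, assigned: pd.Series,
                      mapping: Mapping[str, str] = SUBGROUP_TO_STRATUM) -> float:
    """Mean per-class recall of recovered strata against planted subgroups."""
    truth = pd.Series(truth).map(mapping) if mapping else pd.Series(truth)
    assigned = pd.Series(assigned)
    common = truth.index.intersection(assigned.index)
    truth, assigned = truth.loc[common], assigned.loc[common]
    recalls = []
    for cls in truth.unique():
        sel = truth == cls
        recalls.append(float((assigned[sel] == cls).mean()))
    return float(np.mean(recalls))
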