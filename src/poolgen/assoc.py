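"""Genotype–trait association testing.

Implements the marker–trait machinery of a candidate-gene carcass study:
two-group independent-samples t-tests (pooled variance by default, Welch by
flag), one-way ANOVA across diplotype groups, a fixed-effect linear model

    Y_ij = mu + G_i + S_j + e_ij

with genotype and sex as fixed effects, a trait x locus x stratum scan, and
compact significance letters (a/b at alpha = 0.05, A/B at alpha = 0.01).
No multiple-testing correction is applied by default; a Benjamini–Hochberg
column can be added for honest reuse.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    mean: float
    se: float


@dataclass
class AssociationRow:
    """One tested trait x grouping combination.

    ``letters`` carries compact significance letters: lowercase when the
    pattern separates at alpha = 0.05, uppercase at alpha = 0.01, empty when
    nothing separates. Groups with n < 2 appear in ``groups`` but are
    excluded from the test; n < 3 groups are flagged in ``note``.
    """

    trait: str
    factor: str
    groups: List[GroupSummary]
    stat_name: str  # "t" or "F"
    statistic: float
    df: Tuple[float, ...]
    p: float
    letters: Dict[str, str] = field(default_factory=dict)
    stratum: str = ""
    note: str = ""


def _summary(label: str, values: np.ndarray) -> GroupSummary:
    n = len(values)
    se = float(np.std(values, ddof=1) / np.sqrt(n)) if n >= 2 else float("nan")
    return GroupSummary(label=label, n=n, mean=float(np.mean(values)), se=se)


def _letters_for_p(means: Mapping[str, float], p: float) -> Dict[str, str]:
    """Two-group letters straight from the test's own p-value."""
    order = sorted(means, key=lambda k: -means[k])
    if np.isnan(p) or p >= 0.05:
        return {k: "" for k in means}
    alphabet = "AB" if p < 0.01 else "ab"
    return {lab: alphabet[i] for i, lab in enumerate(order)}


def _pooled_t_p(a: np.ndarray, b: np.ndarray) -> float:
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        return 1.0 if np.mean(a) == np.mean(b) else 0.0
    return float(stats.ttest_ind(a, b, equal_var=True).pvalue)


def t_test_two_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    variant: str = "pooled",
    labels: Tuple[str, str] = ("A", "B"),
    trait: str = "",
    factor: str = "",
) -> AssociationRow:
    """Independent-samples t-test between two genotype groups.

    ``variant="pooled"`` is the classic equal-variance Student t;
    ``"welch"`` drops the equal-variance assumption. Two zero-variance groups
    with equal means give t = 0, p = 1 by convention.
    """
    if variant not in ("pooled", "welch"):
        raise ValueError("variant must be 'pooled' or 'welch'")
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    groups = [_summary(labels[0], a), _summary(labels[1], b)]
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        equal = np.mean(a) == np.mean(b)
        t_stat, p, df = 0.0 if equal else float("inf"), 1.0 if equal else 0.0, len(a) + len(b) - 2.0
    else:
        res = stats.ttest_ind(a, b, equal_var=(variant == "pooled"))
        t_stat, p, df = float(res.statistic), float(res.pvalue), float(res.df)
    letters = _letters_for_p({labels[0]: np.mean(a), labels[1]: np.mean(b)}, p)
    note = _low_n_note(groups)
    return AssociationRow(
        trait=trait,
        factor=factor,
        groups=groups,
        stat_name="t",
        statistic=t_stat,
        df=(df,),
        p=p,
        letters=letters,
        note=note,
    )


def anova_one_way(
    groups: Mapping[str, Sequence[float]],
    trait: str = "",
    factor: str = "",
) -> AssociationRow:
    """One-way ANOVA across genotype or diplotype groups.

    Groups with n < 2 are reported but excluded from the omnibus F test.
    Pairwise letters come from all pairwise pooled t-tests at 0.05 (lowercase)
    and 0.01 (uppercase). With exactly two groups F equals the square of the
    pooled t statistic.
    """
    clean = {
        k: np.asarray(v, dtype=float)[~np.isnan(np.asarray(v, dtype=float))]
        for k, v in groups.items()
    }
    clean = {k: v for k, v in clean.items() if len(v) > 0}
    summaries = [_summary(k, v) for k, v in clean.items()]
    testable = {k: v for k, v in clean.items() if len(v) >= 2}
    note = _low_n_note(summaries)
    if len(testable) < 2:
        return AssociationRow(
            trait=trait,
            factor=factor,
            groups=summaries,
            stat_name="F",
            statistic=float("nan"),
            df=(float("nan"), float("nan")),
            p=float("nan"),
            note=(note + "; " if note else "") + "skipped: fewer than 2 testable groups",
        )
    arrays = list(testable.values())
    f_stat, p = stats.f_oneway(*arrays)
    df1 = len(arrays) - 1
    df2 = sum(len(v) for v in arrays) - len(arrays)
    letters = significance_letters(testable)
    return AssociationRow(
        trait=trait,
        factor=factor,
        groups=summaries,
        stat_name="F",
        statistic=float(f_stat),
        df=(float(df1), float(df2)),
        p=float(p),
        letters=letters,
        note=note,
    )


def _low_n_note(groups: Sequence[GroupSummary]) -> str:
    low = [g.label for g in groups if g.n < 3]
    return f"low-n groups (n < 3): {', '.join(low)}" if low else ""


def _cld(
    means: Mapping[str, float], sig_pairs: Sequence[Tuple[str, str]], uppercase: bool
) -> Dict[str, str]:
    """Compact letter display by insert-and-absorb over significant pairs."""
    labels = sorted(means, key=lambda k: -means[k])
    letter_sets = [set(labels)]
    for a, b in sig_pairs:
        new_sets = []
        for s in letter_sets:
            if a in s and b in s:
                new_sets.extend([s - {a}, s - {b}])
            else:
                new_sets.append(s)
        # absorb subsets
        letter_sets = [
            s
            for i, s in enumerate(new_sets)
            if s and not any(s < t or (s == t and i > j) for j, t in enumerate(new_sets))
        ]
    letter_sets.sort(key=lambda s: -max(means[m] for m in s))
    alphabet = "ABCDEFGH" if uppercase else "abcdefgh"
    out: Dict[str, str] = {lab: "" for lab in labels}
    for letter, s in zip(alphabet, letter_sets):
        for lab in s:
            out[lab] += letter
    return {lab: "".join(sorted(out[lab])) for lab in labels}


def significance_letters(
    groups: Mapping[str, Sequence[float]],
    alphas: Tuple[float, float] = (0.05, 0.01),
) -> Dict[str, str]:
    """Letters from all pairwise pooled t-tests.

    Uppercase letters are used when the pattern already separates at the
    stricter threshold (0.01), lowercase when it separates only at 0.05,
    and no letters when nothing separates — mirroring report-table
    conventions where (a, b) flags p < 0.05 and (A, B) flags p < 0.01.
    """
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    means = {k: float(np.mean(v)) for k, v in arrays.items()}
    pvals = {
        (a, b): _pooled_t_p(arrays[a], arrays[b])
        for a, b in itertools.combinations(arrays, 2)
    }
    loose, strict = max(alphas), min(alphas)
    strict_pairs = [pair for pair, p in pvals.items() if p < strict]
    loose_pairs = [pair for pair, p in pvals.items() if p < loose]
    if strict_pairs and len(strict_pairs) == len(loose_pairs):
        return _cld(means, strict_pairs, uppercase=True)
    if loose_pairs:
        return _cld(means, loose_pairs, uppercase=False)
    return {k: "" for k in arrays}


@dataclass
class GLMResult:
    """Fixed-effect linear model fit Y = mu + genotype + sex + error.

    ``effects`` has one row per fixed effect (F, df, p, from dropping the
    effect's columns); ``params`` are the reference-coded OLS coefficients.
    """

    params: pd.Series
    effects: pd.DataFrame
    resid_var: float
    nobs: int
    dropped: List[str]
    fitted: np.ndarray
    resid: np.ndarray


def glm_fit(
    pop: pd.DataFrame,
    trait: str,
    locus: str,
    sex_col: str = "sex",
    include_sex: bool = True,
) -> GLMResult:
    """OLS fit of a trait on reference-coded genotype and sex fixed effects.

    Rows with a missing trait value are dropped. Effects that are constant
    after subsetting (e.g. sex in a single-sex stratum) are aliased and
    removed, which is logged in ``dropped``; the per-effect F then equals the
    one-way ANOVA F for genotype.
    """
    cols = [trait, locus] + ([sex_col] if include_sex else [])
    data = pop[cols].dropna(subset=[trait, locus]).copy()
    if len(data) < 3:
        raise ValueError(f"too few observations with trait {trait!r}")
    y = data[trait].astype(float).to_numpy()

    factors = {"genotype": data[locus]}
    if include_sex:
        factors["sex"] = data[sex_col]
    dropped = []
    blocks: Dict[str, pd.DataFrame] = {}
    for name, col in factors.items():
        dummies = pd.get_dummies(col, prefix=name, drop_first=True, dtype=float)
        dummies = dummies.loc[:, dummies.nunique() > 1]  # drop aliased columns
        if dummies.shape[1] == 0:
            dropped.append(name)
        else:
            blocks[name] = dummies
    if "genotype" not in blocks:
        raise ValueError(f"genotype at {locus!r} is constant; nothing to estimate")

    X = pd.concat([pd.Series(1.0, index=data.index, name="intercept")] + list(blocks.values()), axis=1)
    full = sm.OLS(y, X).fit()

    rows = []
    for name, block in blocks.items():
        x_red = X.drop(columns=block.columns)
        red = sm.OLS(y, x_red).fit()
        f_stat, p, df_num = full.compare_f_test(red)
        rows.append(
            {
                "effect": name,
                "F": float(f_stat),
                "df_num": float(df_num),
                "df_den": float(full.df_resid),
                "p": float(p),
            }
        )
    return GLMResult(
        params=full.params,
        effects=pd.DataFrame(rows),
        resid_var=float(full.mse_resid),
        nobs=int(full.nobs),
        dropped=dropped,
        fitted=np.asarray(full.fittedvalues),
        resid=np.asarray(full.resid),
    )


def diplotype_column(pop: pd.DataFrame, locus_a: str, locus_b: str) -> pd.Series:
    """Combined two-locus genotype labels like ``"DD-II"``."""
    return pop[locus_a].str.cat(pop[locus_b], sep="-")


def association_scan(
    pop: pd.DataFrame,
    loci: Sequence[str],
    traits: Sequence[str],
    stratify_by_sex: bool = False,
    variant: str = "pooled",
) -> List[AssociationRow]:
    """One association row per trait x locus (x sex stratum).

    Two genotype groups with n >= 2 get a t-test, three or more an ANOVA;
    fewer yields a skipped row with the reason. Individuals of unknown sex
    are excluded from sex strata. Rows are ordered by (trait, locus,
    stratum). No multiple-testing correction is applied; see
    :func:`add_fdr`.
    """
    missing = [c for c in list(loci) + list(traits) if c not in pop.columns]
    if missing:
        raise ValueError(f"unknown columns: {missing}")
    strata: List[Tuple[str, pd.DataFrame]] = (
        [(s, pop[pop["sex"] == s]) for s in ("female", "male")]
        if stratify_by_sex
        else [("", pop)]
    )
    rows: List[AssociationRow] = []
    for trait in sorted(traits):
        for locus in sorted(loci):
            for stratum, sub in strata:
                groups = {
                    geno: grp[trait].dropna().to_numpy()
                    for geno, grp in sub.groupby(locus, observed=True)
                }
                groups = {g: v for g, v in groups.items() if len(v) > 0}
                testable = {g: v for g, v in groups.items() if len(v) >= 2}
                if len(testable) == 2:
                    (la, va), (lb, vb) = sorted(testable.items())
                    row = t_test_two_groups(
                        va, vb, variant=variant, labels=(la, lb), trait=trait, factor=locus
                    )
                    extras = [_summary(g, v) for g, v in groups.items() if g not in testable]
                    row.groups.extend(extras)
                else:
                    row = anova_one_way(groups, trait=trait, factor=locus)
                row.stratum = stratum
                rows.append(row)
    return rows


def rows_to_frame(rows: Sequence[AssociationRow], fdr: bool = False) -> pd.DataFrame:
    """Flatten association rows to a report table (one line per group).

    With ``fdr=True`` a Benjamini–Hochberg adjusted p column is added across
    the distinct tests.
    """
    records = []
    for i, row in enumerate(rows):
        for g in row.groups:
            records.append(
                {
                    "trait": row.trait,
                    "factor": row.factor,
                    "stratum": row.stratum,
                    "group": g.label,
                    "n": g.n,
                    "mean": g.mean,
                    "se": g.se,
                    "letters": row.letters.get(g.label, ""),
                    "stat_name": row.stat_name,
                    "statistic": row.statistic,
                    "p": row.p,
                    "note": row.note,
                    "_test": i,
                }
            )
    columns = [
        "trait", "factor", "stratum", "group", "n", "mean", "se",
        "letters", "stat_name", "statistic", "p", "note", "_test",
    ]
    frame = pd.DataFrame(records, columns=columns)
    if fdr and len(frame):
        pvals = pd.Series({i: rows[i].p for i in frame["_test"].unique()})
        ok = pvals.notna()
        adj = pd.Series(np.nan, index=pvals.index)
        if ok.any():
            adj[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
        frame["p_bh"] = frame["_test"].map(adj)
    return frame.drop(columns="_test")
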