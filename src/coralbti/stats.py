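"""Species-comparison statistics on BTI tables.

Three summaries rank thermal susceptibility and assess the index:

* one-way ANOVA across species with Tukey HSD post-hoc pairs, reported as
  a compact letter display (species sharing a letter are not
  significantly different at the chosen alpha);
* the Pearson correlation between a colony's BTI under the fast and slow
  heating programs, pooled across species — high correlation means the
  two assays rank colonies consistently;
* the within-species coefficient of variation (CV% = 100 * SD / mean over
  colony replicates), the index's repeatability measure.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SpeciesGroupResult",
    "RegimeCorrelation",
    "CVRecord",
    "anova_tukey",
    "tukey_pairwise_pvalues",
    "compact_letter_display",
    "pearson_by_colony",
    "cv_percent",
    "cv_table",
]


@dataclass(frozen=True)
class SpeciesGroupResult:
    """One-way ANOVA + Tukey grouping of species at one cutoff/regime."""

    cutoff: float
    regime: str
    f_stat: float
    p_value: float
    species_means: dict
    species_sds: dict
    letters: dict
    pairwise_p: dict  # {(species_a, species_b): tukey p}
    n_distinguished_pairs: int
    alpha: float


@dataclass(frozen=True)
class RegimeCorrelation:
    """Pearson r between paired FHP and SHP BTIs at one cutoff."""

    cutoff: float
    r: float
    p_value: float
    n_pairs: int


@dataclass(frozen=True)
class CVRecord:
    species: str
    regime: str
    cutoff: float
    cv_percent: float


def tukey_pairwise_pvalues(
    groups: dict[str, np.ndarray],
) -> dict[tuple[str, str], float]:
    """Tukey HSD p-values for all group pairs.

    Degenerate case: when the pooled within-group variance is zero, any
    pair with different means is reported at p = 0 and identical means at
    p = 1 (the studentized range statistic is infinite or undefined).
    """
    names = sorted(groups)
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    pooled_var = np.concatenate(
        [a - a.mean() for a in arrays]
    )
    out: dict[tuple[str, str], float] = {}
    if float(np.sum(pooled_var**2)) == 0.0:
        for i, j in itertools.combinations(range(len(names)), 2):
            same = np.isclose(arrays[i].mean(), arrays[j].mean())
            out[(names[i], names[j])] = 1.0 if same else 0.0
        return out
    res = sps.tukey_hsd(*arrays)
    for i, j in itertools.combinations(range(len(names)), 2):
        out[(names[i], names[j])] = float(res.pvalue[i, j])
    return out


def compact_letter_display(
    names: list[str],
    pairwise_p: dict[tuple[str, str], float],
    alpha: float = 0.05,
) -> dict[str, str]:
    """Assign letters so groups share a letter iff not significantly different.

    Insert-and-absorb procedure: start from one letter covering all
    groups; for each significant pair split the offending letter into two
    sets, then drop letter sets contained in another (absorption).
    Letters are assigned in the order of the (sorted) group names so the
    display is deterministic and permutation-consistent.
    """
    def significant(a: str, b: str) -> bool:
        p = pairwise_p.get((a, b), pairwise_p.get((b, a)))
        if p is None:
            raise KeyError(f"missing pairwise p-value for ({a}, {b})")
        return p < alpha

    names = list(names)
    letter_sets: list[set[str]] = [set(names)]
    for a, b in itertools.combinations(sorted(names), 2):
        if not significant(a, b):
            continue
        new_sets: list[set[str]] = []
        for s in letter_sets:
            if a in s and b in s:
                new_sets.append(s - {a})
                new_sets.append(s - {b})
            else:
                new_sets.append(s)
        # absorb sets contained in another
        letter_sets = [
            s
            for s in new_sets
            if s and not any(s < t for t in new_sets)
        ]
        # deduplicate while keeping order
        seen: list[set[str]] = []
        for s in letter_sets:
            if s not in seen:
                seen.append(s)
        letter_sets = seen

    # order letters by the best (largest) member mean is a plotting nicety;
    # here we order by first member in sorted name order for determinism
    letter_sets.sort(key=lambda s: sorted(names.index(n) for n in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {n: "" for n in names}
    for letter, s in zip(alphabet, letter_sets):
        for n in sorted(s, key=names.index):
            out[n] += letter
    return out


def anova_tukey(
    bti_table: pd.DataFrame,
    cutoff: float,
    regime: str,
    alpha: float = 0.05,
) -> SpeciesGroupResult:
    """One-way ANOVA across species plus Tukey letter groups.

    ``bti_table`` is the long BTI table (columns species, regime, cutoff,
    bti_days).  Species with fewer than 2 finite replicates are excluded
    with a warning.
    """
    sub = bti_table[
        (bti_table["cutoff"] == cutoff) & (bti_table["regime"] == regime)
    ]
    groups: dict[str, np.ndarray] = {}
    for sp, grp in sub.groupby("species"):
        vals = grp["bti_days"].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) < 2:
            warnings.warn(
                f"species {sp!r} excluded: <2 finite BTI replicates",
                UserWarning,
                stacklevel=2,
            )
            continue
        groups[sp] = vals
    if len(groups) < 2:
        raise ValueError("need at least 2 species with >=2 replicates")

    names = sorted(groups)
    arrays = [groups[n] for n in names]
    within_ss = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrays)
    if within_ss == 0.0:
        means = [a.mean() for a in arrays]
        f_stat, p_value = (
            (np.inf, 0.0)
            if np.ptp(means) > 0
            else (np.nan, 1.0)
        )
    else:
        f_stat, p_value = sps.f_oneway(*arrays)
    pairwise = tukey_pairwise_pvalues(groups)
    letters = compact_letter_display(names, pairwise, alpha)
    n_sig = sum(1 for p in pairwise.values() if p < alpha)
    return SpeciesGroupResult(
        cutoff=cutoff,
        regime=regime,
        f_stat=float(f_stat),
        p_value=float(p_value),
        species_means={n: float(groups[n].mean()) for n in names},
        species_sds={n: float(groups[n].std(ddof=1)) for n in names},
        letters=letters,
        pairwise_p=pairwise,
        n_distinguished_pairs=n_sig,
        alpha=alpha,
    )


def pearson_by_colony(
    bti_table: pd.DataFrame, cutoff: float
) -> RegimeCorrelation:
    """Pearson r between FHP and SHP BTIs paired by (species, colony).

    The two fragments cut from each colony — one per heating regime —
    form the pairs; all species are pooled into a single correlation.
    """
    sub = bti_table[bti_table["cutoff"] == cutoff]
    piv = sub.pivot_table(
        index=["species", "colony"],
        columns="regime",
        values="bti_days",
        aggfunc="first",
    )
    if "FHP" not in piv.columns or "SHP" not in piv.columns:
        raise ValueError("need both FHP and SHP observations")
    piv = piv.dropna(subset=["FHP", "SHP"])
    if len(piv) < 3:
        raise ValueError("need at least 3 complete colony pairs")
    x = piv["FHP"].to_numpy(dtype=float)
    y = piv["SHP"].to_numpy(dtype=float)
    if np.var(x) == 0.0 or np.var(y) == 0.0:
        raise ValueError("zero variance in one regime; r undefined")
    r, p = sps.pearsonr(x, y)
    return RegimeCorrelation(
        cutoff=cutoff, r=float(r), p_value=float(p), n_pairs=len(piv)
    )


def cv_percent(values) -> float:
    """Coefficient of variation: 100 * sample SD (n-1) / mean."""
    vals = np.asarray(values, dtype=float)
    if len(vals) < 2:
        raise ValueError("need at least 2 values")
    mean = float(vals.mean())
    if mean == 0.0:
        raise ValueError("mean is zero; CV undefined")
    return 100.0 * float(vals.std(ddof=1)) / mean


def cv_table(
    bti_table: pd.DataFrame,
    cutoffs: tuple[float, ...] = (10.0, 20.0, 30.0, 40.0, 50.0),
) -> pd.DataFrame:
    """Per species x regime x cutoff CV% of BTI over colony replicates."""
    rows = []
    for (sp, regime), grp in bti_table.groupby(["species", "regime"]):
        for cut in cutoffs:
            vals = grp.loc[grp["cutoff"] == cut, "bti_days"].to_numpy(float)
            vals = vals[np.isfinite(vals)]
            if len(vals) < 2:
                continue
            rows.append(
                {
                    "species": sp,
                    "regime": regime,
                    "cutoff": cut,
                    "cv_percent": cv_percent(vals),
                }
            )
    return pd.DataFrame(rows)
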