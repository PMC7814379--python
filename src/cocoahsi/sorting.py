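"""Predicted-fat sorting: fraction selection and reference comparison.

Emulates a manual segregation trial: rank beans by model-predicted fat,
pull the k highest into a "high" fraction and the k lowest into "low",
sample an "average" fraction from the remainder, then test whether the
fractions differ on their *reference* fat values.  Pairwise Welch
(unequal-variance) t-tests at alpha=0.05 with no multiplicity
correction are the default (a Holm option exists); results are
summarised as a compact letter display.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError


def select_fractions(per_bean_pred: pd.DataFrame, k_high: int, k_low: int,
                     k_mid: int = 0, seed: int = 0) -> pd.DataFrame:
    """Assign beans to high / low / average fractions by predicted fat.

    ``per_bean_pred`` needs columns ``bean_id`` and ``predicted_fat``.
    Ties at a fraction boundary resolve toward the lower bean id.  The
    "average" fraction is a uniform (seeded) sample of the remainder.
    Returns the frame with a ``fraction`` column ("high", "low",
    "average" or "" for unassigned).
    """
    df = per_bean_pred.reset_index(drop=True).copy()
    n = len(df)
    if k_high + k_low + k_mid > n:
        raise ValueError(
            f"k_high+k_low+k_mid = {k_high + k_low + k_mid} exceeds {n} beans")
    df["fraction"] = ""
    by_pred = df.sort_values(["predicted_fat", "bean_id"],
                             ascending=[False, True], kind="stable")
    high_ids = by_pred["bean_id"].iloc[:k_high].to_numpy()
    by_pred_lo = df.sort_values(["predicted_fat", "bean_id"],
                                ascending=[True, True], kind="stable")
    low_ids = by_pred_lo["bean_id"].iloc[:k_low].to_numpy()
    if np.intersect1d(high_ids, low_ids).size:
        raise ValueError("high and low fractions overlap; lower k_high/k_low")
    df.loc[df["bean_id"].isin(high_ids), "fraction"] = "high"
    df.loc[df["bean_id"].isin(low_ids), "fraction"] = "low"
    if k_mid:
        remainder = df.loc[df["fraction"] == "", "bean_id"].to_numpy()
        rng = np.random.default_rng(seed)
        mid_ids = rng.choice(np.sort(remainder), size=k_mid, replace=False)
        df.loc[df["bean_id"].isin(mid_ids), "fraction"] = "average"
    return df


def compact_letter_display(groups: list, nonsig: set) -> dict:
    """Letters such that two groups share one iff their pair is in ``nonsig``.

    ``nonsig`` holds frozensets of group pairs that are *not*
    significantly different.  Every group shares a letter with itself.
    Implemented as a clique cover of the non-significance graph (groups
    are few, so exhaustive maximal-clique enumeration is fine).
    """
    adj = {g: {g} for g in groups}
    for pair in nonsig:
        a, b = tuple(pair)
        adj[a].add(b)
        adj[b].add(a)

    # maximal cliques by subset enumeration (k is tiny)
    cliques = []
    members = list(groups)
    for size in range(len(members), 0, -1):
        for combo in combinations(members, size):
            if all(b in adj[a] for a, b in combinations(combo, 2)):
                cset = set(combo)
                if not any(cset <= c for c in cliques):
                    cliques.append(cset)
    # stable order: cliques containing earlier groups first
    cliques.sort(key=lambda c: min(members.index(g) for g in c))
    letters = {g: "" for g in groups}
    for i, clique in enumerate(cliques):
        letter = chr(ord("a") + i)
        for g in groups:
            if g in clique:
                letters[g] += letter
    return letters


def compare_fractions(assignment: pd.DataFrame, reference_col: str = "fat_as_is",
                      alpha: float = 0.05, holm: bool = False) -> dict:
    """Welch pairwise t-tests between fractions on reference values.

    Returns group means/sds/counts, the pairwise p-values, and the
    compact letter display (groups sharing a letter do not differ
    significantly at ``alpha``).
    """
    df = assignment[assignment["fraction"] != ""]
    groups = sorted(df["fraction"].unique(),
                    key=lambda g: -df.loc[df["fraction"] == g, reference_col].mean())
    values = {g: df.loc[df["fraction"] == g, reference_col].to_numpy(dtype=float)
              for g in groups}
    for g, v in values.items():
        if v.size < 2:
            raise ValueError(f"fraction {g!r} has {v.size} member(s); need >= 2")
    pvals = {}
    degenerate = []
    for a, b in combinations(groups, 2):
        if values[a].std(ddof=1) == 0 and values[b].std(ddof=1) == 0:
            degenerate.append((a, b))
            # identical constants are indistinguishable; differing constants differ
            pvals[frozenset((a, b))] = 1.0 if values[a].mean() == values[b].mean() else 0.0
            continue
        _, p = stats.ttest_ind(values[a], values[b], equal_var=False)
        pvals[frozenset((a, b))] = float(p)
    if holm:
        keys = sorted(pvals, key=pvals.get)
        m = len(keys)
        adjusted, running = {}, 0.0
        for i, k in enumerate(keys):
            running = max(running, min(1.0, (m - i) * pvals[k]))
            adjusted[k] = running
        pvals = adjusted
    nonsig = {k for k, p in pvals.items() if p >= alpha}
    letters = compact_letter_display(groups, nonsig)
    summary = pd.DataFrame({
        "fraction": groups,
        "mean": [values[g].mean() for g in groups],
        "sd": [values[g].std(ddof=1) for g in groups],
        "n": [values[g].size for g in groups],
        "letters": [letters[g] for g in groups],
    })
    if degenerate and all(values[g].std(ddof=1) == 0 for g in groups):
        raise DegenerateInputError("all fractions have zero variance")
    return {"summary": summary,
            "p_values": {tuple(sorted(k)): p for k, p in pvals.items()},
            "letters": letters}


def enrichment(assignment: pd.DataFrame, reference_col: str = "fat_as_is") -> dict:
    """High-minus-low and high-minus-overall mean fat differences."""
    df = assignment
    high = df.loc[df["fraction"] == "high", reference_col].to_numpy(dtype=float)
    low = df.loc[df["fraction"] == "low", reference_col].to_numpy(dtype=float)
    if high.size == 0 or low.size == 0:
        raise ValueError("high and low fractions must be non-empty")
    overall = df[reference_col].to_numpy(dtype=float)
    return {
        "high_minus_low": float(high.mean() - low.mean()),
        "high_minus_overall": float(high.mean() - overall.mean()),
        "high_mean": float(high.mean()), "low_mean": float(low.mean()),
        "high_sd": float(high.std(ddof=1)) if high.size > 1 else 0.0,
        "low_sd": float(low.std(ddof=1)) if low.size > 1 else 0.0,
    }
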