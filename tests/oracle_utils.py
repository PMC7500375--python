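"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (explicit loops, dictionaries of means)
that share no code with the package internals they validate.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd


def brute_local_maxima(x) -> list[int]:
    """Every local maximum by direct neighbour comparison; plateaus take the
    first sample of the run."""
    x = list(map(float, x))
    n = len(x)
    out = []
    i = 1
    while i < n - 1:
        if x[i] > x[i - 1]:
            j = i
            while j + 1 < n and x[j + 1] == x[i]:
                j += 1
            if j + 1 < n and x[j + 1] < x[i]:
                out.append(i)
            i = j + 1
        else:
            i += 1
    return out


def brute_peaks(rate, i0: int, i1: int, frac: float = 0.3):
    """(global peak, first-qualifying peak) by exhaustive scan of [i0, i1)."""
    w = list(map(float, rate[i0:i1]))
    peak = max(w)
    maxima = [w[i] for i in brute_local_maxima(w)]
    qualifying = [m for m in maxima if m >= frac * peak]
    first = qualifying[0] if qualifying else peak
    return peak, first


def brute_split_plot_anova(cells: pd.DataFrame) -> dict[str, float]:
    """Split-plot ANOVA F values via explicit dictionary-of-means loops.

    Expects tidy columns participant, group, tms_condition, order_pair,
    value, with a balanced complete design.  Returns {effect: F}.
    """
    df = cells.copy()
    df["previous"] = df["order_pair"].str[0].map({"L": "light", "H": "heavy"})
    df["current"] = df["order_pair"].str[1].map({"L": "light", "H": "heavy"})
    factors = {
        "condition": sorted(df["tms_condition"].unique()),
        "previous": ["light", "heavy"],
        "current": ["light", "heavy"],
    }
    subjects = sorted(df["participant"].unique())
    groups = sorted(df["group"].unique())
    group_of = dict(
        df.drop_duplicates("participant")[["participant", "group"]].values
    )
    val = {}
    for _, r in df.iterrows():
        val[(r["participant"], r["tms_condition"], r["previous"], r["current"])] = r[
            "value"
        ]

    def mean(keys):
        return sum(val[k] for k in keys) / len(keys)

    all_cells = list(
        itertools.product(
            subjects, factors["condition"], factors["previous"], factors["current"]
        )
    )
    grand = mean(all_cells)
    m_cells = 12

    def subj_cells(s):
        return [c for c in all_cells if c[0] == s]

    def marg(s_set, levels):
        # mean over subjects in s_set and cells matching the partial levels
        keys = [
            c
            for c in all_cells
            if c[0] in s_set
            and all(c[i + 1] == l for i, l in enumerate(levels) if l is not None)
        ]
        return mean(keys)

    fidx = {"condition": 0, "previous": 1, "current": 2}
    out = {}

    # between stratum
    subj_mean = {s: mean(subj_cells(s)) for s in subjects}
    grp_mean = {
        g: np.mean([subj_mean[s] for s in subjects if group_of[s] == g])
        for g in groups
    }
    ss_subj = m_cells * sum(
        (subj_mean[s] - grp_mean[group_of[s]]) ** 2 for s in subjects
    )
    df_subj = len(subjects) - len(groups)
    if len(groups) > 1:
        ss_g = m_cells * sum(
            sum(1 for s in subjects if group_of[s] == g) * (grp_mean[g] - grand) ** 2
            for g in groups
        )
        out["location"] = (ss_g / (len(groups) - 1)) / (ss_subj / df_subj)

    names = list(factors)
    for k in range(1, 4):
        for subset in itertools.combinations(names, k):
            combos = list(itertools.product(*[factors[f] for f in subset]))

            def levels_of(combo):
                lv = [None, None, None]
                for f, l in zip(subset, combo):
                    lv[fidx[f]] = l
                return tuple(lv)

            # interaction contrast by inclusion-exclusion over sub-subsets
            def contrast(s_set, combo, weight_fn):
                tot = 0.0
                for r in range(len(subset) + 1):
                    for sub2 in itertools.combinations(range(len(subset)), r):
                        lv = [None, None, None]
                        for i in sub2:
                            lv[fidx[subset[i]]] = combo[i]
                        sign = (-1) ** (len(subset) - r)
                        tot += sign * weight_fn(s_set, tuple(lv))
                return tot

            rest = int(
                np.prod([len(factors[f]) for f in names if f not in subset])
            )
            n_subj = len(subjects)

            ss_w = n_subj * rest * sum(
                contrast(subjects, c, marg) ** 2 for c in combos
            )
            df_w = int(np.prod([len(factors[f]) - 1 for f in subset]))

            # error: subject-by-effect interaction within groups
            ss_err = 0.0
            for s in subjects:
                g = group_of[s]
                g_set = [x for x in subjects if group_of[x] == g]
                for c in combos:
                    ss_err += (
                        contrast([s], c, marg) - contrast(g_set, c, marg)
                    ) ** 2
            ss_err *= rest
            df_err = df_subj * df_w
            name = ":".join(subset)
            out[name] = (ss_w / df_w) / (ss_err / df_err)

            if len(groups) > 1:
                ss_gw = 0.0
                for g in groups:
                    g_set = [x for x in subjects if group_of[x] == g]
                    for c in combos:
                        ss_gw += len(g_set) * (
                            contrast(g_set, c, marg) - contrast(subjects, c, marg)
                        ) ** 2
                ss_gw *= rest
                df_gw = (len(groups) - 1) * df_w
                out["location:" + name] = (ss_gw / df_gw) / (ss_err / df_err)
    return out
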