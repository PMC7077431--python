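"""Frost-damage physiology: electrolyte-leakage damage index, winterkill
ratings, and group comparisons by one-way ANOVA with protected Fisher's LSD.

The electrolyte-leakage damage index for a genotype x temperature cell is

    D_I = 100 (R_t - R_o) / (1 - R_o)

where R_t is the mean initial/final conductivity ratio (EC_i / EC_f) of
frozen replicates and R_o the same ratio for unfrozen controls.  R_o < 1 is
required (a control that has fully leaked carries no information).  Ratios
are averaged across replicates, not conductivities, because the index is
defined on per-sample ratios.  With measurement noise D_I can fall slightly
below 0 or above 100; it is reported unclamped with a clamped companion.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class DamageIndex:
    genotype: str
    temperature: float
    di: float
    di_clamped: float
    r_t: float
    r_o: float
    n_frozen: int
    n_control: int


def damage_index(
    ec_i_frozen: Sequence[float],
    ec_f_frozen: Sequence[float],
    ec_i_control: Sequence[float],
    ec_f_control: Sequence[float],
    genotype: str = "",
    temperature: float = float("nan"),
) -> DamageIndex:
    """Damage index from replicate conductivity pairs of one cell."""
    fro_i, fro_f = np.asarray(ec_i_frozen, float), np.asarray(ec_f_frozen, float)
    con_i, con_f = np.asarray(ec_i_control, float), np.asarray(ec_f_control, float)
    if len(fro_i) == 0 or len(con_i) == 0:
        raise ValueError("need at least one frozen and one control replicate")
    for arr in (fro_i, fro_f, con_i, con_f):
        if (arr <= 0).any():
            raise ValueError("conductivities must be positive")
    r_t = float(np.mean(fro_i / fro_f))
    r_o = float(np.mean(con_i / con_f))
    if r_o >= 1:
        raise ValueError("control fully leaked (R_o >= 1)")
    di = 100.0 * (r_t - r_o) / (1.0 - r_o)
    return DamageIndex(
        genotype=genotype,
        temperature=temperature,
        di=di,
        di_clamped=float(np.clip(di, 0.0, 100.0)),
        r_t=r_t,
        r_o=r_o,
        n_frozen=len(fro_i),
        n_control=len(con_i),
    )


def damage_index_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Per genotype x temperature damage indices from a freeze-trial table.

    Expects the conductivity schema of
    :func:`coldsig.simulate.simulate_el_table` (one frozen and one control
    EC pair per replicate row).
    """
    rows = []
    for (genotype, temperature), cell in trials.groupby(
        ["genotype", "temperature"], sort=False
    ):
        res = damage_index(
            cell["ec_i_frozen"],
            cell["ec_f_frozen"],
            cell["ec_i_control"],
            cell["ec_f_control"],
            genotype=str(genotype),
            temperature=float(temperature),
        )
        species = cell["species"].iloc[0] if "species" in cell else str(genotype)
        rows.append(
            {
                "genotype": res.genotype,
                "species": species,
                "temperature": res.temperature,
                "di": res.di,
                "di_clamped": res.di_clamped,
                "r_t": res.r_t,
                "r_o": res.r_o,
                "n_replicates": res.n_frozen,
            }
        )
    return pd.DataFrame(rows)


def winterkill_rating(percent_damage: float, resprouted: bool) -> int:
    """Map percent twig damage to the ordinal 1-5 winterkill scale.

    Bands are left-closed, right-open: [0,5) -> 1 (no visible damage),
    [5,20) -> 2 (minimal), [20,50) -> 3 (moderate), [50,90) -> 4 (severe,
    dieback with resprouting).  In the [90,100] zone the resprout flag
    separates severe damage (4) from mortal injury (5).
    """
    if not 0 <= percent_damage <= 100:
        raise ValueError("percent damage must lie in [0, 100]")
    if percent_damage < 5:
        return 1
    if percent_damage < 20:
        return 2
    if percent_damage < 50:
        return 3
    if percent_damage < 90:
        return 4
    return 4 if resprouted else 5


# ---------------------------------------------------------------------------
# one-way ANOVA with protected Fisher's LSD


@dataclass
class AnovaLsdResult:
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    mse: float
    group_means: dict
    group_n: dict
    protected: bool  # LSD applied (ANOVA significant at alpha)
    pairwise: pd.DataFrame  # group_a, group_b, diff, lsd, significant
    letters: dict  # compact letter display, group -> letters string
    alpha: float


def _compact_letters(groups: Sequence[str], significant_pairs: set) -> dict:
    """Insert-and-absorb compact letter display.

    Guarantees: groups in a significant pair never share a letter; groups in
    a non-significant pair share at least one letter.
    """
    sets: list[set] = [set(groups)]
    for a, b in significant_pairs:
        new_sets = []
        for s in sets:
            if a in s and b in s:
                new_sets.append(s - {a})
                new_sets.append(s - {b})
            else:
                new_sets.append(s)
        # absorb subsets
        sets = []
        for s in sorted(new_sets, key=len, reverse=True):
            if s and not any(s <= t for t in sets):
                sets.append(s)
    order = {g: i for i, g in enumerate(groups)}
    sets.sort(key=lambda s: min(order[g] for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in groups}
    for i, s in enumerate(sets):
        for g in groups:
            if g in s:
                letters[g] += alphabet[i % len(alphabet)]
    return letters


def anova_lsd(
    values: Sequence[float],
    groups: Sequence[str],
    alpha: float = 0.05,
) -> AnovaLsdResult:
    """One-way fixed-effects ANOVA with protected Fisher's LSD.

    Pairwise least-significant-difference comparisons are only performed
    when the omnibus ANOVA is significant at ``alpha`` (the "protection"
    that controls the type-I error of the letter display).  With zero
    residual variance the omnibus test is degenerate: any difference in
    means is then declared significant.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(groups)
    names = list(pd.unique(labels))
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    samples = [values[labels == g] for g in names]
    if any(len(s) < 1 for s in samples):
        raise ValueError("every group needs at least one observation")
    n_total = len(values)
    k = len(names)
    df_b = k - 1
    df_w = n_total - k
    if df_w < 2:
        raise ValueError("need at least 2 residual degrees of freedom")
    grand = values.mean()
    ss_b = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    ss_w = sum(((s - s.mean()) ** 2).sum() for s in samples)
    mse = ss_w / df_w
    means = {g: float(s.mean()) for g, s in zip(names, samples)}
    ns = {g: len(s) for g, s in zip(names, samples)}
    if mse == 0:
        distinct = len(set(means.values())) > 1
        f = math.inf if distinct else 0.0
        p = 0.0 if distinct else 1.0
    else:
        f = (ss_b / df_b) / mse
        p = float(sps.f.sf(f, df_b, df_w))
    protected = p <= alpha
    pairs = []
    sig_pairs = set()
    tcrit = sps.t.ppf(1 - alpha / 2.0, df_w)
    for a, b in itertools.combinations(names, 2):
        diff = abs(means[a] - means[b])
        lsd = (
            tcrit * math.sqrt(mse * (1.0 / ns[a] + 1.0 / ns[b])) if mse > 0 else 0.0
        )
        sig = bool(protected and (diff > lsd if mse > 0 else diff > 0))
        if sig:
            sig_pairs.add((a, b))
        pairs.append(
            {"group_a": a, "group_b": b, "diff": diff, "lsd": lsd, "significant": sig}
        )
    order = sorted(names, key=lambda g: -means[g])
    letters = _compact_letters(order, sig_pairs | {(b, a) for a, b in sig_pairs})
    return AnovaLsdResult(
        f_statistic=float(f),
        p_value=p,
        df_between=df_b,
        df_within=df_w,
        mse=float(mse),
        group_means=means,
        group_n=ns,
        protected=protected,
        pairwise=pd.DataFrame(pairs),
        letters=letters,
        alpha=alpha,
    )


def group_summary(
    records: pd.DataFrame,
    value: str,
    keys: Sequence[str] = ("species", "temperature"),
) -> pd.DataFrame:
    """Mean, SE (= sd/sqrt(n), NA for singletons) and n per group cell."""
    rows = []
    for key_vals, cell in records.groupby(list(keys), sort=False):
        if not isinstance(key_vals, tuple):
            key_vals = (key_vals,)
        x = cell[value].to_numpy(dtype=float)
        n = len(x)
        se = float(np.std(x, ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
        row = dict(zip(keys, key_vals))
        row.update({"mean": float(x.mean()), "se": se, "n": n})
        rows.append(row)
    return pd.DataFrame(rows)
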