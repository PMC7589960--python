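"""Two-way crossed PERMANOVA with permutation and Monte-Carlo p-values.

The total sum of squares of a distance matrix D is partitioned through
the Gower-centred inner-product matrix

    G = (I - 11'/n) (-D^2/2) (I - 11'/n),

whose trace is the total SS. The SS of a model term is the trace of
``P G`` where ``P`` projects onto the span of that term's centred dummy
variables; for a balanced crossed design the main-effect, interaction
and residual subspaces are mutually orthogonal, so

    SS_A + SS_B + SS_AxB + SS_res = SS_total

holds exactly. Pseudo-F ratios test each term against the residual mean
square. p(perm) comes from unrestricted permutation of observation
labels — exact for balanced fixed-effects designs under the global null
— with the observed statistic included in the reference set:
p = (b + 1)/(m + 1). Where few unique permutations exist (small
two-group contrasts) an asymptotic Monte-Carlo p(MC) is drawn from
eigenvalue-weighted chi-square ratios of the centred inner-product
spectrum; in the univariate Euclidean case this reduces to the exact
F distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .design import TwoWayDesign

_PERM_BLOCK = 1000


def gower_center(d: np.ndarray) -> np.ndarray:
    """Gower-centred inner-product matrix of a distance matrix."""
    d = np.asarray(d, dtype=float)
    a = -0.5 * d**2
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _projection(x: np.ndarray) -> np.ndarray:
    """Orthogonal projection onto the column space of x (rank-safe)."""
    return x @ np.linalg.pinv(x)


def _centered_dummies(labels) -> np.ndarray:
    labels = list(labels)
    levels = sorted(set(labels), key=str)
    x = np.zeros((len(labels), len(levels)))
    for i, lab in enumerate(labels):
        x[i, levels.index(lab)] = 1.0
    return x - x.mean(axis=0)


@dataclass
class PermanovaResult:
    table: pd.DataFrame  # rows: A, B, A x B, Residual, Total
    pairwise: pd.DataFrame | None = None


def _term_projections(design: TwoWayDesign):
    xa = _centered_dummies(design.a)
    xb = _centered_dummies(design.b)
    cells = [f"{a}\x00{b}" for a, b in zip(design.a, design.b)]
    xc = _centered_dummies(cells)
    pa, pb, pc = _projection(xa), _projection(xb), _projection(xc)
    return pa, pb, pc


def permanova_two_way(
    dist,
    design: TwoWayDesign,
    n_perm: int = 9999,
    seed: int = 0,
) -> PermanovaResult:
    """Two-way crossed PERMANOVA on a distance matrix.

    ``dist`` is an n x n symmetric distance matrix (array or DataFrame)
    aligned with the design's observation order. Returns a result whose
    table has one row per source (A, B, A x B, Residual, Total) with df,
    SS, MS, pseudo-F, p(perm) and the count of unique permutation
    statistics.
    """
    if n_perm < 999:
        raise ValueError("n_perm must be >= 999")
    d = np.asarray(dist, dtype=float)
    if d.shape != (design.n, design.n):
        raise ValueError("distance matrix does not match design size")
    g = gower_center(d)
    ss_total = float(np.trace(g))
    if ss_total <= 0:
        raise ValueError("total sum of squares is zero; pseudo-F undefined")

    pa, pb, pc = _term_projections(design)
    dfs = design.df
    names = list(dfs)  # [A, B, AxB, Residual, Total]
    df_a, df_b, df_ab, df_res = (dfs[k] for k in names[:4])

    def term_ss(gm: np.ndarray) -> tuple[float, float, float, float]:
        ss_a = float(np.sum(pa * gm))
        ss_b = float(np.sum(pb * gm))
        ss_model = float(np.sum(pc * gm))
        return ss_a, ss_b, ss_model - ss_a - ss_b, float(np.trace(gm)) - ss_model

    ss_a, ss_b, ss_ab, ss_res = term_ss(g)
    ms_res = ss_res / df_res
    f_obs = np.array(
        [ss_a / df_a / ms_res, ss_b / df_b / ms_res, ss_ab / df_ab / ms_res]
    )

    rng = np.random.default_rng(seed)
    exceed = np.zeros(3)
    stats_seen: list[list[float]] = [[], [], []]
    done = 0
    while done < n_perm:
        m = min(_PERM_BLOCK, n_perm - done)
        perms = np.array([rng.permutation(design.n) for _ in range(m)])
        gp = g[perms[:, :, None], perms[:, None, :]]
        t_a = np.einsum("ij,mij->m", pa, gp)
        t_b = np.einsum("ij,mij->m", pb, gp)
        t_c = np.einsum("ij,mij->m", pc, gp)
        ss_res_p = ss_total - t_c
        ms_res_p = ss_res_p / df_res
        f_p = np.stack(
            [
                t_a / df_a / ms_res_p,
                t_b / df_b / ms_res_p,
                (t_c - t_a - t_b) / df_ab / ms_res_p,
            ]
        )
        exceed += (f_p >= f_obs[:, None] - 1e-12).sum(axis=1)
        for i in range(3):
            stats_seen[i].append(f_p[i])
        done += m

    p_perm = (exceed + 1.0) / (n_perm + 1.0)
    unique = [
        int(np.unique(np.round(np.concatenate(s), 10)).size) for s in stats_seen
    ]

    rows = []
    for i, (name, ss, dfv) in enumerate(
        zip(names[:3], (ss_a, ss_b, ss_ab), (df_a, df_b, df_ab))
    ):
        rows.append(
            {
                "source": name, "df": dfv, "SS": ss, "MS": ss / dfv,
                "pseudo_F": f_obs[i], "p_perm": p_perm[i], "unique_perms": unique[i],
            }
        )
    rows.append(
        {"source": "Residual", "df": df_res, "SS": ss_res, "MS": ms_res,
         "pseudo_F": np.nan, "p_perm": np.nan, "unique_perms": np.nan}
    )
    rows.append(
        {"source": "Total", "df": dfs["Total"], "SS": ss_total, "MS": np.nan,
         "pseudo_F": np.nan, "p_perm": np.nan, "unique_perms": np.nan}
    )
    return PermanovaResult(pd.DataFrame(rows))


def _two_group_f(g: np.ndarray, mask: np.ndarray) -> float:
    """One-way two-group pseudo-F from a Gower matrix and a group mask."""
    n = g.shape[0]
    x = np.column_stack([mask.astype(float)])
    x = x - x.mean(axis=0)
    p = _projection(x)
    ss_b = float(np.sum(p * g))
    ss_t = float(np.trace(g))
    ss_w = ss_t - ss_b
    return (ss_b / 1.0) / (ss_w / (n - 2))


def _montecarlo_p(g: np.ndarray, f_obs: float, df1: int, df2: int,
                  n_draws: int, rng: np.random.Generator) -> float:
    """Asymptotic Monte-Carlo p: eigenvalue-weighted chi-square ratio draws."""
    lam = np.linalg.eigvalsh(g)
    lam = lam[lam > max(1e-10 * lam.max(), 0.0)]
    if lam.size == 0:
        return float("nan")
    u = rng.chisquare(df1, size=(n_draws, lam.size))
    v = rng.chisquare(df2, size=(n_draws, lam.size))
    f_star = (u @ lam / df1) / (v @ lam / df2)
    return float(((f_star >= f_obs - 1e-12).sum() + 1.0) / (n_draws + 1.0))


def pairwise_permanova(
    dist,
    design: TwoWayDesign,
    n_perm: int = 9999,
    seed: int = 0,
    n_mc: int = 10_000,
    contrasts: list[tuple] | None = None,
    max_exhaustive: int = 10_000,
) -> pd.DataFrame:
    """Pairwise two-group contrasts of factor B within each level of factor A.

    Each contrast is a one-way two-group PERMANOVA on the subset;
    t = sqrt(pseudo-F). p(perm) is exhaustive whenever the number of
    group assignments is tractable (it always is at n = 3 + 3, where only
    10 distinct splits exist — flagged as low-resolution), sampled
    otherwise. p(MC) draws >= ``n_mc`` eigenvalue-weighted chi-square
    ratios from the subset's centred inner-product spectrum.

    ``contrasts`` restricts the factor-B level pairs (list of 2-tuples);
    default is all pairs.
    """
    d = np.asarray(dist, dtype=float)
    rng = np.random.default_rng(seed)
    a_arr = np.array(design.a, dtype=object)
    b_arr = np.array(design.b, dtype=object)
    pairs = contrasts or list(combinations(design.b_levels, 2))
    rows = []
    for la in design.a_levels:
        for lb1, lb2 in pairs:
            idx = np.flatnonzero(
                (a_arr == la) & ((b_arr == lb1) | (b_arr == lb2))
            )
            mask = b_arr[idx] == lb1
            n1, n2 = int(mask.sum()), int((~mask).sum())
            if n1 < 2 or n2 < 2:
                raise ValueError(
                    f"contrast ({la}, {lb1} vs {lb2}) needs >= 2 observations per side"
                )
            sub = d[np.ix_(idx, idx)]
            g = gower_center(sub)
            f_obs = _two_group_f(g, mask)
            n = n1 + n2
            n_assign = comb(n, n1)
            distinct_splits = n_assign // 2 if n1 == n2 else n_assign
            if n_assign <= max_exhaustive:
                stats = []
                for chosen in combinations(range(n), n1):
                    m = np.zeros(n, dtype=bool)
                    m[list(chosen)] = True
                    stats.append(_two_group_f(g, m))
                stats = np.asarray(stats)
                p_perm = float((stats >= f_obs - 1e-12).mean())
                n_used = n_assign
                exhaustive = True
            else:
                stats = np.empty(n_perm)
                for i in range(n_perm):
                    perm = rng.permutation(n)
                    stats[i] = _two_group_f(g, mask[perm])
                p_perm = float(((stats >= f_obs - 1e-12).sum() + 1.0) / (n_perm + 1.0))
                n_used = n_perm
                exhaustive = False
            p_mc = _montecarlo_p(g, f_obs, 1, n - 2, n_mc, rng)
            rows.append(
                {
                    "a_level": la, "b_level_1": lb1, "b_level_2": lb2,
                    "t": float(np.sqrt(max(f_obs, 0.0))),
                    "p_perm": p_perm, "p_mc": p_mc,
                    "n_perms_used": n_used, "exhaustive": exhaustive,
                    "distinct_splits": distinct_splits,
                    "low_resolution": distinct_splits < 100,
                }
            )
    return pd.DataFrame(rows)
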