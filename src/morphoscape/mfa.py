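"""Multi-way factor analysis (MFA) of the year-wise structure-function tables.

Each observation year contributes one 9 (functions) × 7 (structures) table
of mean patch size.  Tables are column-standardised, down-weighted so no
single year dominates, concatenated column-wise and decomposed by SVD:

* classical MFA weighting (default): each table is scaled by 1/σ₁, the
  inverse of its largest singular value, so every table's first axis has
  unit inertia;
* STATIS weighting: table weights from the leading eigenvector of the RV
  matrix, favouring the years most similar to the consensus.

Eigenvalues are those of the cross-product of the weighted concatenated
table (squared singular values); axes with eigenvalue > 1 are retained.
Per-year partial loadings (structures) and partial scores (functions) place
each year in the common "compromise" space, and the RV coefficient matrix
summarises between-year configuration similarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class StandardizedTable:
    """A column-standardised year table plus its MFA weight α."""

    year: int
    values: pd.DataFrame
    alpha: float = 1.0


@dataclass
class MfaResult:
    """Global decomposition plus per-year projections.

    eigenvalues are non-increasing; percent_variance sums to 100 over all
    axes; rv is symmetric with unit diagonal.
    """

    eigenvalues: np.ndarray
    percent_variance: np.ndarray
    n_retained: int
    partial_loadings: dict[int, pd.DataFrame]
    partial_scores: dict[int, pd.DataFrame]
    rv: pd.DataFrame
    variant: str
    weights: dict[int, float] = field(default_factory=dict)

    def axis_names(self) -> list[str]:
        return [f"axis{i + 1}" for i in range(self.n_retained)]


def standardize(table: pd.DataFrame) -> pd.DataFrame:
    """Column z-scores with the population (n) divisor; constant columns → 0."""
    X = table.to_numpy(dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)  # population variance, deterministic contract
    Z = np.where(sd > 0, (X - mu) / np.where(sd == 0, 1.0, sd), 0.0)
    return pd.DataFrame(Z, index=table.index, columns=table.columns)


def table_weight(table: pd.DataFrame) -> float:
    """Classical MFA weight α = 1/σ₁² of a standardised table."""
    X = table.to_numpy(dtype=float)
    s1 = np.linalg.svd(X, compute_uv=False)[0]
    if s1 <= 0:
        raise ValueError("all-zero table has no defined MFA weight")
    return float(1.0 / s1**2)


def rv_coefficient(a: pd.DataFrame, b: pd.DataFrame) -> float:
    """RV configuration similarity in [0, 1] between two same-row tables.

    RV = tr(Sa·Sb)/√(tr(Sa²)·tr(Sb²)) with S = X·Xᵀ; invariant to scaling
    and to orthogonal row rotations applied to both tables.
    """
    Xa, Xb = a.to_numpy(dtype=float), b.to_numpy(dtype=float)
    if Xa.shape[0] != Xb.shape[0]:
        raise ValueError("tables must share their rows")
    Sa, Sb = Xa @ Xa.T, Xb @ Xb.T
    denom = np.sqrt(np.trace(Sa @ Sa) * np.trace(Sb @ Sb))
    if denom == 0:
        raise ValueError("RV undefined for an all-zero table")
    return float(np.trace(Sa @ Sb) / denom)


def statis_weights(tables: dict[int, pd.DataFrame]) -> dict[int, float]:
    """STATIS table weights: leading eigenvector of the RV matrix, scaled to sum 1."""
    years = sorted(tables)
    n = len(years)
    R = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            R[i, j] = R[j, i] = rv_coefficient(tables[years[i]], tables[years[j]])
    vals, vecs = np.linalg.eigh(R)
    lead = np.abs(vecs[:, np.argmax(vals)])
    lead = lead / lead.sum()
    return {y: float(w) for y, w in zip(years, lead)}


def _canonical_signs(V: np.ndarray) -> np.ndarray:
    """Sign per axis making the largest-magnitude loading positive."""
    idx = np.argmax(np.abs(V), axis=0)
    signs = np.sign(V[idx, np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    return signs


def fit(
    tables: dict[int, pd.DataFrame],
    variant: str = "mfa",
    min_retained: int = 1,
) -> MfaResult:
    """Fit the multi-way factor analysis on standardised year tables.

    Parameters
    ----------
    tables
        Mapping year → standardised table (shared row index).
    variant
        "mfa" for 1/σ₁² weights, "statis" for RV-eigenvector weights.
    min_retained
        Floor on the number of retained axes (the eigenvalue-greater-than-1
        rule can retain none on weakly structured data).
    """
    if variant not in {"mfa", "statis"}:
        raise ValueError(f"variant must be 'mfa' or 'statis', got {variant!r}")
    years = sorted(tables)
    if not years:
        raise ValueError("no tables given")
    n_tables = len(years)

    if variant == "mfa":
        weights = {y: table_weight(tables[y]) for y in years}
    else:
        weights = statis_weights(tables)

    blocks = [tables[y].to_numpy(dtype=float) * np.sqrt(weights[y]) for y in years]
    G = np.hstack(blocks)
    if not np.any(G):
        raise ValueError("rank-0 input: all tables are zero after weighting")

    U, s, Vt = np.linalg.svd(G, full_matrices=False)
    eigenvalues = s**2
    percent = 100.0 * eigenvalues / eigenvalues.sum()
    n_retained = max(int((eigenvalues > 1.0).sum()), int(min_retained))
    n_retained = min(n_retained, len(eigenvalues))

    V = Vt.T[:, :n_retained]
    signs = _canonical_signs(V)
    V = V * signs
    U_r = U[:, :n_retained] * signs

    axis_names = [f"axis{i + 1}" for i in range(n_retained)]
    col_starts = np.cumsum([0] + [b.shape[1] for b in blocks])
    partial_loadings: dict[int, pd.DataFrame] = {}
    partial_scores: dict[int, pd.DataFrame] = {}
    for k, y in enumerate(years):
        Vk = V[col_starts[k]: col_starts[k + 1], :]
        # column coordinates: singular-value-scaled loadings for this year
        partial_loadings[y] = pd.DataFrame(
            Vk * s[:n_retained] / np.sqrt(G.shape[0]),
            index=tables[y].columns,
            columns=axis_names,
        )
        # partial row scores, rescaled by the number of tables so their
        # average over years is the global score
        Fk = n_tables * blocks[k] @ Vk
        partial_scores[y] = pd.DataFrame(Fk, index=tables[y].index, columns=axis_names)

    R = pd.DataFrame(np.eye(n_tables), index=years, columns=years)
    for i, yi in enumerate(years):
        for j in range(i + 1, n_tables):
            yj = years[j]
            R.loc[yi, yj] = R.loc[yj, yi] = rv_coefficient(tables[yi], tables[yj])

    return MfaResult(
        eigenvalues=eigenvalues,
        percent_variance=percent,
        n_retained=n_retained,
        partial_loadings=partial_loadings,
        partial_scores=partial_scores,
        rv=R,
        variant=variant,
        weights=weights,
    )


def align_axes(
    result: MfaResult,
    reference: pd.DataFrame,
) -> MfaResult:
    """Flip/permute retained axes to best match reference coordinates.

    ``reference`` is a long table with columns (entity, year, axis, value).
    For every permutation-free greedy assignment the axis whose loadings
    correlate best (in absolute value) with each reference axis is chosen
    and its sign set to make the correlation positive.  Downstream
    displacement statistics are invariant to this step; it only eases
    side-by-side reading against published coordinates.
    """
    years = sorted(result.partial_loadings)
    ref = reference.pivot_table(index=["entity", "year"], columns="axis", values="value")
    obs = pd.concat(
        {
            y: pd.concat([result.partial_loadings[y], result.partial_scores[y]])
            for y in years
        },
        names=["year", "entity"],
    ).swaplevel().sort_index()

    common = obs.index.intersection(ref.index)
    if common.empty:
        return result
    O = obs.loc[common].to_numpy(dtype=float)
    R = ref.loc[common].to_numpy(dtype=float)

    n_axes = min(O.shape[1], R.shape[1])
    corr = np.zeros((R.shape[1], O.shape[1]))
    for i in range(R.shape[1]):
        for j in range(O.shape[1]):
            denom = R[:, i].std() * O[:, j].std()
            corr[i, j] = 0.0 if denom == 0 else np.corrcoef(R[:, i], O[:, j])[0, 1]

    perm, signs, used = [], [], set()
    for i in range(n_axes):
        order = np.argsort(-np.abs(corr[i]))
        j = next(int(jj) for jj in order if int(jj) not in used)
        used.add(j)
        perm.append(j)
        signs.append(1.0 if corr[i, j] >= 0 else -1.0)

    def _apply(df: pd.DataFrame) -> pd.DataFrame:
        out = df.iloc[:, perm].to_numpy() * np.asarray(signs)
        return pd.DataFrame(out, index=df.index, columns=[f"axis{i+1}" for i in range(len(perm))])

    return MfaResult(
        eigenvalues=result.eigenvalues,
        percent_variance=result.percent_variance,
        n_retained=len(perm),
        partial_loadings={y: _apply(df) for y, df in result.partial_loadings.items()},
        partial_scores={y: _apply(df) for y, df in result.partial_scores.items()},
        rv=result.rv,
        variant=result.variant + "+aligned",
        weights=result.weights,
    )
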