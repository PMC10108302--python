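"""Pedigree, genomic and combined relationship matrices.

The genetic relationship used by the prediction models is a weighted blend
H = w*A + (1-w)*Gs of the recursive pedigree kinship matrix A and the
VanRaden marker kinship G affinely rescaled to match A (Gs).  Marker data
pass through the standard QC pipeline first: missingness/MAF filtering,
random-forest imputation, and correlation-based pruning.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "compute_pedigree_kinship",
    "filter_markers",
    "impute_markers",
    "prune_markers",
    "compute_genomic_kinship",
    "scale_g_to_a",
    "combine_h",
]


# ---------------------------------------------------------------------------
# pedigree kinship
# ---------------------------------------------------------------------------

def _topological_order(ped: pd.DataFrame) -> list[str]:
    parents = {r.id: [p for p in (r.parent1, r.parent2) if pd.notna(p)]
               for r in ped.itertuples(index=False)}
    order: list[str] = []
    state: dict[str, int] = {}  # 0 visiting, 1 done

    for root in parents:
        if root in state:
            continue
        stack = [(root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                state[node] = 1
                order.append(node)
                continue
            if state.get(node) == 1:
                continue
            if state.get(node) == 0:
                raise ValueError(f"pedigree cycle involving {node!r}")
            state[node] = 0
            stack.append((node, True))
            for p in parents.get(node, []):
                if p not in parents:
                    raise ValueError(f"unknown parent {p!r} of {node!r}")
                if state.get(p) == 0:
                    raise ValueError(f"pedigree cycle involving {p!r}")
                if state.get(p) != 1:
                    stack.append((p, False))
    return order


def compute_pedigree_kinship(pedigree: pd.DataFrame) -> pd.DataFrame:
    """Recursive (tabular) kinship for an inbred-line pedigree.

    Standard recursion phi(i,j) = (phi(p1,j) + phi(p2,j)) / 2 with unrelated
    founders at phi = 0.  Self-kinship reflects the extra selfing
    generations of inbred-line development: with g generations the line's
    inbreeding coefficient is F = 1 - (1 - phi(p1,p2)) * 2^-g (founders:
    F = 1 - 2^-g), giving phi(i,i) = (1 + F) / 2 close to one, as expected
    for fully developed inbred lines.
    """
    ped = pedigree.set_index("id", drop=False)
    if ped.index.has_duplicates:
        raise ValueError("duplicate pedigree ids")
    order = _topological_order(pedigree)
    idx = {g: i for i, g in enumerate(order)}
    n = len(order)
    gens = ped["inbreeding_gens"] if "inbreeding_gens" in ped else pd.Series(6, index=ped.index)
    K = np.zeros((n, n))
    for g_id in order:
        i = idx[g_id]
        rec = ped.loc[g_id]
        p1, p2 = rec["parent1"], rec["parent2"]
        g = int(gens.loc[g_id])
        if pd.isna(p1) or pd.isna(p2):
            parent_phi = 0.0
        else:
            j1, j2 = idx[p1], idx[p2]
            K[i, :] = 0.5 * (K[j1, :] + K[j2, :])
            K[:, i] = K[i, :]
            parent_phi = K[j1, j2]
        F = 1.0 - (1.0 - parent_phi) * 2.0 ** (-g)
        K[i, i] = 0.5 * (1.0 + F)
    labels = pedigree["id"].tolist()
    perm = [idx[g] for g in labels]
    out = pd.DataFrame(K[np.ix_(perm, perm)], index=labels, columns=labels)
    out.attrs["kind"] = "A"
    return out


# ---------------------------------------------------------------------------
# marker QC pipeline
# ---------------------------------------------------------------------------

def _maf(col: pd.Series) -> float:
    p = col.mean(skipna=True) / 2.0
    return float(min(p, 1.0 - p))


def filter_markers(markers: pd.DataFrame, max_missing: float = 0.10,
                   min_maf: float = 0.05) -> pd.DataFrame:
    """Drop markers with > ``max_missing`` missingness or MAF < ``min_maf``.

    Both boundaries are inclusive for retention: 10% missing and MAF
    exactly 0.05 survive.  Column order is preserved.
    """
    miss = markers.isna().mean(axis=0)
    maf = markers.apply(_maf, axis=0)
    keep = (miss <= max_missing) & (maf >= min_maf)
    out = markers.loc[:, keep]
    if out.shape[1] == 0:
        raise ValueError("all markers removed by missingness/MAF filters")
    return out


def impute_markers(markers: pd.DataFrame, seed: int = 0, n_iter: int = 5,
                   n_trees: int = 30) -> pd.DataFrame:
    """Iterative per-column random-forest imputation of missing calls.

    Missing cells start at the column mode; for up to ``n_iter`` rounds
    each incomplete column is re-predicted from all other columns with a
    random-forest classifier fitted on its observed rows.  Stops early when
    an iteration changes nothing.  Output calls are in {0, 1, 2}.
    """
    from sklearn.ensemble import RandomForestClassifier

    if not markers.isna().any().any():
        return markers.copy()
    if markers.isna().all(axis=0).any():
        bad = markers.columns[markers.isna().all(axis=0)][0]
        raise ValueError(f"column {bad!r} is fully missing; filter first")
    X = markers.to_numpy(dtype=float)
    na = np.isnan(X)
    filled = X.copy()
    for j in range(X.shape[1]):
        if na[:, j].any():
            vals, counts = np.unique(X[~na[:, j], j], return_counts=True)
            filled[na[:, j], j] = vals[np.argmax(counts)]
    incomplete = np.flatnonzero(na.any(axis=0))
    rng = np.random.default_rng(seed)
    for _ in range(n_iter):
        changed = False
        for j in incomplete:
            obs = ~na[:, j]
            others = np.delete(np.arange(X.shape[1]), j)
            y_obs = X[obs, j].astype(int)
            if len(np.unique(y_obs)) == 1:
                pred = np.full(na[:, j].sum(), y_obs[0])
            else:
                clf = RandomForestClassifier(
                    n_estimators=n_trees,
                    random_state=int(rng.integers(2**31 - 1)))
                clf.fit(filled[obs][:, others], y_obs)
                pred = clf.predict(filled[~obs][:, others])
            if not np.array_equal(filled[~obs, j], pred.astype(float)):
                filled[~obs, j] = pred
                changed = True
        if not changed:
            break
    return pd.DataFrame(filled, index=markers.index, columns=markers.columns)


def prune_markers(markers: pd.DataFrame, r_max: float = 0.8) -> pd.DataFrame:
    """Greedy left-to-right correlation pruning.

    Scanning markers in map order, a marker is kept unless its absolute
    Pearson correlation with any already-kept marker exceeds ``r_max``.
    Zero-variance markers are dropped with a warning (their correlation is
    undefined).
    """
    X = markers.to_numpy(dtype=float)
    n, m = X.shape
    sd = X.std(axis=0)
    mean = X.mean(axis=0)
    kept: list[int] = []
    Z = np.empty_like(X)
    for j in range(m):
        if sd[j] == 0:
            warnings.warn(f"dropping zero-variance marker "
                          f"{markers.columns[j]!r}", stacklevel=2)
            continue
        z = (X[:, j] - mean[j]) / sd[j]
        if kept:
            r = Z[:, kept].T @ z / n
            if np.any(np.abs(r) > r_max):
                continue
        Z[:, j] = z
        kept.append(j)
    if not kept:
        raise ValueError("all markers removed by pruning")
    return markers.iloc[:, kept]


# ---------------------------------------------------------------------------
# genomic kinship and blending
# ---------------------------------------------------------------------------

def compute_genomic_kinship(markers: pd.DataFrame) -> pd.DataFrame:
    """VanRaden marker kinship G = M M' / p with column-standardised M.

    Each marker column is centred and scaled to unit (population) standard
    deviation, so the mean diagonal of G is exactly one.
    """
    X = markers.to_numpy(dtype=float)
    if X.shape[1] == 0:
        raise ValueError("no markers")
    if np.isnan(X).any():
        raise ValueError("markers contain missing calls; impute first")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("zero-variance marker; prune first")
    M = (X - X.mean(axis=0)) / sd
    G = M @ M.T / M.shape[1]
    out = pd.DataFrame(G, index=markers.index, columns=markers.index)
    out.attrs["kind"] = "G"
    return out


def _mean_moments(K: np.ndarray) -> tuple[float, float]:
    n = len(K)
    diag = float(np.mean(np.diag(K)))
    off = float((K.sum() - np.trace(K)) / (n * (n - 1)))
    return diag, off


def scale_g_to_a(G: pd.DataFrame, A: pd.DataFrame) -> pd.DataFrame:
    """Affinely rescale G so its moments match A on shared genotypes.

    Gs = a + b*G with (a, b) solving mean(diag(Gs)) = mean(diag(A)) and
    mean(offdiag(Gs)) = mean(offdiag(A)) over the shared label set.  This
    puts the marker kinship on the pedigree scale before blending into H.
    """
    shared = [g for g in G.index if g in set(A.index)]
    if len(shared) < 2:
        raise ValueError("need >= 2 shared genotypes to match moments")
    Gm = G.loc[shared, shared].to_numpy()
    Am = A.loc[shared, shared].to_numpy()
    g_diag, g_off = _mean_moments(Gm)
    a_diag, a_off = _mean_moments(Am)
    denom = g_diag - g_off
    if abs(denom) < 1e-12:
        raise ValueError("G has no diagonal/off-diagonal contrast; "
                         "cannot determine scale")
    b = (a_diag - a_off) / denom
    a = a_diag - b * g_diag
    out = a + b * G
    out.attrs["kind"] = "Gs"
    return out


def combine_h(A: pd.DataFrame, Gs: pd.DataFrame,
              omega: float = 0.2) -> pd.DataFrame:
    """Blend pedigree and scaled marker kinship: H = w*A + (1-w)*Gs.

    The blend applies on pairs where both genotypes carry marker data; any
    pair involving an ungenotyped line keeps its plain A value.  Output is
    labelled on A's full label set.
    """
    if not (0.0 <= omega <= 1.0):
        raise ValueError("omega must be in [0, 1]")
    if not set(Gs.index) <= set(A.index):
        raise ValueError("Gs labels must be a subset of A labels")
    H = A.copy().astype(float)
    genotyped = [g for g in A.index if g in set(Gs.index)]
    block = (omega * A.loc[genotyped, genotyped]
             + (1.0 - omega) * Gs.loc[genotyped, genotyped])
    H.loc[genotyped, genotyped] = block
    H.attrs["kind"] = "H"
    return H
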