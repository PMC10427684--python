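"""Fingerprint distance matrices and low-dimensional chemical-space maps.

Structures are compared as Morgan radius-2 bit fingerprints (2048 bits by
default) under Tanimoto distance. Two projections are offered: a native
Sammon mapping — nonlinear metric scaling that minimizes

    E = (1 / sum_{i<j} delta_ij) * sum_{i<j} (delta_ij - d_ij)^2 / delta_ij

where delta are input distances and d the embedded Euclidean distances,
so that errors on small distances are weighted most heavily — and a thin
adapter over UMAP for large collections. Before mapping reaction-partner
sets, the shared boronic acid/ester handle can be replaced in silico by a
methyl group so the map reflects the variable portion of each reagent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

from .chem_core import mol_from_smiles

_EPS = 1e-12


@dataclass
class EmbeddingResult:
    coordinates: np.ndarray  # n x dims
    stress: float
    iterations_used: int
    converged: bool
    stress_history: list[float]


def morgan_fingerprint_matrix(
    smiles: list[str], radius: int = 2, n_bits: int = 2048
) -> np.ndarray:
    """Dense 0/1 fingerprint matrix (rows = molecules)."""
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    out = np.zeros((len(smiles), n_bits), dtype=np.uint8)
    for i, s in enumerate(smiles):
        fp = gen.GetFingerprint(mol_from_smiles(s))
        arr = np.zeros((n_bits,), dtype=np.uint8)
        DataStructs.ConvertToNumpyArray(fp, arr)
        out[i] = arr
    return out


def tanimoto_distance_matrix(fps: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto distance 1 - |i&j|/|i|j| for binary fingerprints.

    Two all-zero fingerprints are identically empty: their distance is
    defined as 0.
    """
    if fps.ndim != 2 or fps.shape[0] == 0:
        raise ValueError("need a non-empty 2-D fingerprint matrix")
    f = fps.astype(np.float64)
    inter = f @ f.T
    popcount = f.sum(axis=1)
    union = popcount[:, None] + popcount[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.where(union > 0, inter / union, 1.0)
    d = 1.0 - sim
    np.fill_diagonal(d, 0.0)
    return d


# --- boronate handling ------------------------------------------------------

_BORON = Chem.MolFromSmarts("[#5;X3]([#8])[#8]")


def replace_boronate_with_methyl(smiles: str) -> tuple[str, bool]:
    """Replace a boronic acid/ester group with a methyl at the attachment atom.

    The boron and its oxygen substituents (with any pinacol carbons, which
    become disconnected) are removed and a methyl carbon is placed on the
    former boron neighbor. An acid and its pinacol ester collapse to the
    same structure. Molecules without a boron group are returned unchanged
    with ``replaced=False``.
    """
    mol = mol_from_smiles(smiles)
    match = mol.GetSubstructMatch(_BORON)
    if not match:
        return Chem.MolToSmiles(mol), False
    b_idx = match[0]
    b_atom = mol.GetAtomWithIdx(b_idx)
    oxygens = [nb.GetIdx() for nb in b_atom.GetNeighbors() if nb.GetAtomicNum() == 8]
    anchor = next(
        (nb.GetIdx() for nb in b_atom.GetNeighbors() if nb.GetAtomicNum() != 8), None
    )
    rw = Chem.RWMol(mol)
    if anchor is not None:
        methyl = Chem.Atom(6)
        methyl.SetAtomMapNum(99)  # transient marker to locate the kept fragment
        c_idx = rw.AddAtom(methyl)
        rw.AddBond(anchor, c_idx, Chem.BondType.SINGLE)
    for idx in sorted([b_idx] + oxygens, reverse=True):
        rw.RemoveAtom(idx)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    # pinacol carbons form a disconnected fragment; keep the anchored one
    frags = Chem.GetMolFrags(out, asMols=True, sanitizeFrags=True)
    best = next(
        f for f in frags
        if any(a.GetAtomMapNum() == 99 for a in f.GetAtoms())
    )
    for atom in best.GetAtoms():
        atom.SetAtomMapNum(0)
    return Chem.MolToSmiles(best), True


# --- Sammon mapping ---------------------------------------------------------


def _validate_distances(dist: np.ndarray) -> np.ndarray:
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(dist, dist.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if np.any(dist < 0):
        raise ValueError("distance matrix must be non-negative")
    return dist


def classical_mds(dist: np.ndarray, dims: int = 2) -> np.ndarray:
    """Classical (Torgerson) metric scaling used as Sammon initialization."""
    n = dist.shape[0]
    d2 = dist**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:dims]
    vals = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(vals)


def sammon_stress(dist: np.ndarray, coords: np.ndarray) -> float:
    iu = np.triu_indices(dist.shape[0], k=1)
    delta = np.maximum(dist[iu], _EPS)
    diff = coords[:, None, :] - coords[None, :, :]
    d = np.sqrt((diff**2).sum(-1))[iu]
    return float(((delta - d) ** 2 / delta).sum() / delta.sum())


def _sammon_descend(
    dist: np.ndarray,
    coords: np.ndarray,
    max_iter: int,
    tol: float,
    magic: float = 0.35,
) -> tuple[np.ndarray, float, int, bool, list[float]]:
    """One Sammon optimization run from a given configuration.

    Uses the classic pseudo-Newton update (gradient scaled by the absolute
    diagonal of the Hessian, damped by the "magic factor"), with step
    halving whenever a proposed update would increase the stress — so the
    stress trace is non-increasing over accepted iterations.
    """
    n = dist.shape[0]
    delta = np.maximum(dist, _EPS)
    np.fill_diagonal(delta, 1.0)  # diagonal excluded via masking below
    c = np.maximum(dist[np.triu_indices(n, k=1)], _EPS).sum()
    mask = ~np.eye(n, dtype=bool)

    def stress_of(x: np.ndarray) -> float:
        diff = x[:, None, :] - x[None, :, :]
        d = np.sqrt((diff**2).sum(-1))
        np.fill_diagonal(d, 1.0)
        return float(((dist - d) ** 2 / delta)[mask].sum() / (2.0 * c))

    stress = stress_of(coords)
    history = [stress]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        diff = coords[:, None, :] - coords[None, :, :]
        d = np.sqrt((diff**2).sum(-1))
        np.fill_diagonal(d, 1.0)
        d = np.maximum(d, _EPS)
        # first and (absolute) second partial derivatives, Sammon's form
        w1 = (dist - d) / (delta * d)
        np.fill_diagonal(w1, 0.0)
        grad = -(2.0 / c) * (w1[:, :, None] * diff).sum(axis=1)
        w2a = 1.0 / (delta * d)
        np.fill_diagonal(w2a, 0.0)
        hess = (2.0 / c) * (
            w2a[:, :, None] * (diff**2) / d[:, :, None] ** 2
            + w1[:, :, None] * (1.0 - (diff**2) / d[:, :, None] ** 2)
        ).sum(axis=1)
        denom = np.maximum(np.abs(hess), _EPS)
        delta_step = grad / denom
        accepted = False
        s = magic
        for _ in range(30):
            cand = coords - s * delta_step
            cand_stress = stress_of(cand)
            if cand_stress <= stress:
                accepted = True
                break
            s *= 0.5
        if not accepted:
            converged = True
            break
        improvement = stress - cand_stress
        coords, stress = cand, cand_stress
        history.append(stress)
        if improvement < tol:
            converged = True
            break
    return coords, stress, it, converged, history


def sammon_map(
    dist_matrix: np.ndarray,
    dims: int = 2,
    max_iter: int = 500,
    tol: float = 1e-12,
    seed: int = 0,
    n_init: int = 30,
    init: np.ndarray | None = None,
) -> EmbeddingResult:
    """Minimize the Sammon stress; deterministic given ``seed``.

    Runs the pseudo-Newton Sammon iteration from classical metric scaling
    plus ``n_init - 1`` seeded random configurations (the stress surface
    is multimodal) and returns the best run. Zero input distances are
    floored at 1e-12 in the denominators. An explicit ``init`` disables
    the restarts.
    """
    dist = _validate_distances(dist_matrix)
    n = dist.shape[0]
    if n < dims + 1:
        raise ValueError(f"need at least {dims + 1} points for a {dims}-D map")
    rng = np.random.default_rng(seed)
    scale = dist.max() if dist.max() > 0 else 1.0
    if init is not None:
        inits = [np.array(init, dtype=float)]
    else:
        mds = classical_mds(dist, dims) + 1e-6 * rng.standard_normal((n, dims))
        inits = [mds] + [
            scale * rng.standard_normal((n, dims)) for _ in range(max(0, n_init - 1))
        ]
    best: EmbeddingResult | None = None
    for start in inits:
        coords, stress, it, converged, history = _sammon_descend(
            dist, start, max_iter=max_iter, tol=tol
        )
        if best is None or stress < best.stress:
            best = EmbeddingResult(
                coordinates=coords,
                stress=stress,
                iterations_used=it,
                converged=converged,
                stress_history=history,
            )
    assert best is not None
    return best


def umap_view(
    fps: np.ndarray | None = None,
    dist_matrix: np.ndarray | None = None,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    seed: int = 0,
) -> np.ndarray:
    """Thin adapter over the UMAP backend; not a reimplementation.

    Accepts either a fingerprint matrix (embedded under Jaccard metric) or
    a precomputed distance matrix. A single point bypasses the backend and
    sits at the origin.
    """
    try:
        import umap
    except ImportError as exc:  # pragma: no cover
        raise RuntimeError("UMAP backend is not available") from exc
    if (fps is None) == (dist_matrix is None):
        raise ValueError("pass exactly one of fps or dist_matrix")
    n = fps.shape[0] if fps is not None else dist_matrix.shape[0]
    if n == 1:
        return np.zeros((1, 2))
    if dist_matrix is not None:
        reducer = umap.UMAP(
            n_neighbors=min(n_neighbors, n - 1), min_dist=min_dist,
            metric="precomputed", random_state=seed,
        )
        return reducer.fit_transform(_validate_distances(dist_matrix))
    reducer = umap.UMAP(
        n_neighbors=min(n_neighbors, n - 1), min_dist=min_dist,
        metric="jaccard", random_state=seed,
    )
    return reducer.fit_transform(fps)


def subsample_rows(n_total: int, n_sample: int, seed: int = 0) -> np.ndarray:
    """Seeded, reproducible row selection for large-library background maps."""
    rng = np.random.default_rng(seed)
    if n_sample >= n_total:
        return np.arange(n_total)
    return np.sort(rng.choice(n_total, size=n_sample, replace=False))
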