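"""Fingerprint similarity, clustering and budget pruning.

Similarity currency: extended-connectivity fingerprints of diameter 4
(ECFP4, i.e. Morgan radius 2) hashed to a fixed-length bit vector, compared
with Tanimoto similarity.  Clustering into k diversity groups uses k-means
on the raw bit vectors by default, with a k-medoids alternative that works
directly in Tanimoto distance.  Budget pruning greedily removes the
worse-scoring member of the currently most-similar pair until a target
count remains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator
from sklearn.cluster import KMeans

from evoscreen.errors import InputError

logger = logging.getLogger(__name__)

_FP_GENERATORS: dict[tuple[int, int], object] = {}


@dataclass(frozen=True)
class Fingerprint:
    """An ECFP bitset keyed by canonical SMILES."""

    molecule_key: str
    bitvect: DataStructs.ExplicitBitVect

    @property
    def n_bits(self) -> int:
        return self.bitvect.GetNumBits()

    def on_bits(self) -> tuple[int, ...]:
        return tuple(self.bitvect.GetOnBits())

    def to_array(self) -> np.ndarray:
        arr = np.zeros(self.n_bits, dtype=np.uint8)
        DataStructs.ConvertToNumpyArray(self.bitvect, arr)
        return arr


def fingerprint(smiles: str, n_bits: int = 2048, radius: int = 2) -> Fingerprint:
    """ECFP fingerprint (diameter = 2 × radius; default ECFP4, 2048 bits)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InputError(f"unparsable SMILES: {smiles!r}")
    key = (radius, n_bits)
    if key not in _FP_GENERATORS:
        _FP_GENERATORS[key] = rdFingerprintGenerator.GetMorganGenerator(
            radius=radius, fpSize=n_bits
        )
    bv = _FP_GENERATORS[key].GetFingerprint(mol)
    return Fingerprint(molecule_key=Chem.MolToSmiles(mol), bitvect=bv)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """|a AND b| / |a OR b|; 0/0 is defined as 0."""
    if a.n_bits != b.n_bits:
        raise InputError(
            f"fingerprint length mismatch: {a.n_bits} vs {b.n_bits}"
        )
    if a.bitvect.GetNumOnBits() == 0 and b.bitvect.GetNumOnBits() == 0:
        return 0.0
    return DataStructs.TanimotoSimilarity(a.bitvect, b.bitvect)


@dataclass
class ClusterAssignment:
    """Molecule-to-cluster mapping with optional per-cluster representatives."""

    assignments: dict[str, int]  # molecule key -> cluster id in [0, k)
    k: int
    representatives: dict[int, str] = field(default_factory=dict)

    def members(self, cluster_id: int) -> list[str]:
        return [key for key, cid in self.assignments.items() if cid == cluster_id]


def _kmedoids(dist: np.ndarray, k: int, rng: np.random.Generator,
              max_iter: int = 100) -> np.ndarray:
    """Plain alternating k-medoids on a precomputed distance matrix."""
    n = dist.shape[0]
    medoids = rng.choice(n, size=k, replace=False)
    labels = np.argmin(dist[:, medoids], axis=1)
    for _ in range(max_iter):
        new_medoids = medoids.copy()
        for c in range(k):
            members = np.flatnonzero(labels == c)
            if members.size == 0:
                continue
            within = dist[np.ix_(members, members)].sum(axis=1)
            new_medoids[c] = members[int(np.argmin(within))]
        new_labels = np.argmin(dist[:, new_medoids], axis=1)
        if np.array_equal(new_medoids, medoids) and np.array_equal(new_labels, labels):
            break
        medoids, labels = new_medoids, new_labels
    return labels


def cluster_compounds(
    fingerprints: list[Fingerprint],
    k: int = 100,
    seed: int = 0,
    scores: dict[str, float] | None = None,
    method: str = "kmeans",
) -> ClusterAssignment:
    """Cluster fingerprints into at most ``k`` diversity groups.

    ``method='kmeans'`` runs k-means on the raw bit vectors (the k-means
    centroid is undefined under Tanimoto, so the literal-metric alternative
    ``method='kmedoids'`` is provided).  Seeded and reproducible; empty
    clusters are dropped and ids relabeled contiguously.  When per-molecule
    ``scores`` (lid_root2, lower = better) are supplied, each cluster's
    representative is its best-scoring member.
    """
    if not fingerprints:
        raise InputError("no fingerprints to cluster")
    if k < 1:
        raise InputError("k must be >= 1")
    keys = [fp.molecule_key for fp in fingerprints]
    n_distinct = len(set(keys))
    if k > n_distinct:
        logger.warning("k=%d exceeds %d distinct molecules; reducing", k, n_distinct)
        k = n_distinct

    rng = np.random.default_rng(seed)
    if method == "kmeans":
        X = np.stack([fp.to_array() for fp in fingerprints]).astype(float)
        km = KMeans(n_clusters=k, random_state=int(rng.integers(2**31)), n_init=10)
        labels = km.fit_predict(X)
    elif method == "kmedoids":
        n = len(fingerprints)
        dist = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = 1.0 - tanimoto(fingerprints[i], fingerprints[j])
                dist[i, j] = dist[j, i] = d
        labels = _kmedoids(dist, k, rng)
    else:
        raise InputError(f"unknown clustering method {method!r}")

    # drop empty clusters, relabel contiguously in first-seen order
    relabel: dict[int, int] = {}
    assignments: dict[str, int] = {}
    for key, lab in zip(keys, labels):
        cid = relabel.setdefault(int(lab), len(relabel))
        assignments[key] = cid

    representatives: dict[int, str] = {}
    if scores is not None:
        for key, cid in assignments.items():
            best = representatives.get(cid)
            if best is None or (scores[key], key) < (scores[best], best):
                representatives[cid] = key
    return ClusterAssignment(
        assignments=assignments, k=len(relabel), representatives=representatives
    )


@dataclass(frozen=True)
class PruneRemoval:
    """One step of the budget-pruning audit trail."""

    step: int
    removed_key: str
    kept_key: str
    similarity: float
    removed_score: float
    kept_score: float


def similarity_budget_prune(
    scored: list[tuple[str, float]],
    n_target: int,
    n_bits: int = 2048,
) -> tuple[list[tuple[str, float]], list[PruneRemoval]]:
    """Greedy diversity pruning down to exactly ``n_target`` molecules.

    ``scored`` is a list of (canonical SMILES key, lid_root2) pairs.  At
    each step the currently most-similar pair (pairwise ECFP4 Tanimoto) is
    found and its worse-scoring member (higher lid_root2) removed; this
    repeats until ``n_target`` remain.  Ties in similarity are broken by
    key order of the pair; ties in score keep the lexicographically earlier
    key.  Returns (kept molecules in input order, removal audit trail).
    """
    if len(scored) < n_target:
        raise InputError(
            f"cannot prune {len(scored)} molecules down to {n_target}"
        )
    keys = [k for k, _ in scored]
    if len(set(keys)) != len(keys):
        raise InputError("duplicate molecule keys in prune input")
    score = dict(scored)
    fps = [fingerprint(k, n_bits=n_bits) for k in keys]
    n = len(keys)
    sim = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = tanimoto(fps[i], fps[j])

    active = list(range(n))
    removals: list[PruneRemoval] = []
    step = 0
    while len(active) > n_target:
        best_pair = None
        best_sim = -1.0
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                s = sim[i, j]
                pair_key = tuple(sorted((keys[i], keys[j])))
                if s > best_sim or (
                    s == best_sim and best_pair is not None
                    and pair_key < tuple(sorted((keys[best_pair[0]], keys[best_pair[1]])))
                ):
                    best_sim = s
                    best_pair = (i, j)
        i, j = best_pair
        ki, kj = keys[i], keys[j]
        # worse score = higher lid_root2; ties keep the earlier key
        if (score[ki], ki) > (score[kj], kj):
            removed, kept = i, j
        else:
            removed, kept = j, i
        step += 1
        removals.append(PruneRemoval(
            step=step, removed_key=keys[removed], kept_key=keys[kept],
            similarity=float(best_sim),
            removed_score=score[keys[removed]], kept_score=score[keys[kept]],
        ))
        active.remove(removed)
    kept_set = {keys[i] for i in active}
    return [(k, s) for k, s in scored if k in kept_set], removals
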