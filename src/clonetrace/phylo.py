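"""Mitochondrial consensus, p-distances, bootstrapped NJ trees, clade report.

Maternal lineages are read off an alignment of per-sample mitochondrial
consensus sequences: pairwise p-distances (proportion of differing
unambiguous sites) feed a neighbor-joining tree, and branch confidence comes
from the nonparametric bootstrap — alignment columns are resampled with
replacement, the tree is rebuilt per replicate, and each internal branch of
the full-data tree is annotated with the percentage of completed replicates
containing the same bipartition. Replicates with an undefined distance pair
(no comparable sites) are skipped, counted and logged.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .simulate import ALPHABET, derived_rng
from .trees import (
    DistanceMatrix,
    bipartitions,
    collapse_zero_branches,
    nj_tree,
)

logger = logging.getLogger(__name__)

_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(ALPHABET):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def _encode(seq: str) -> np.ndarray:
    """ACGT -> 0..3; anything else (N, gaps, ambiguity codes) -> 4."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def mito_consensus(pileup: np.ndarray, sample_id: str | None = None) -> str:
    """Plurality-base consensus from per-site base counts (L x 4, ACGT order).

    Ties between top bases and zero-coverage sites emit N.
    """
    counts = np.asarray(pileup)
    if counts.ndim != 2 or counts.shape[1] != 4:
        raise ValueError("pileup must be an (L, 4) array of base counts")
    if np.any(counts < 0):
        raise ValueError("pileup counts must be nonnegative")
    mx = counts.max(axis=1)
    n_at_max = (counts == mx[:, None]).sum(axis=1)
    chars = np.array(list(ALPHABET))[np.argmax(counts, axis=1)]
    chars[(mx == 0) | (n_at_max > 1)] = "N"
    return "".join(chars)


def p_distance(a: str, b: str) -> float:
    """Mismatches / compared sites; sites with N (or any ambiguity) in either
    sequence are excluded from numerator and denominator."""
    if len(a) != len(b):
        raise ValueError(f"sequences must have equal length ({len(a)} vs {len(b)})")
    ca, cb = _encode(a), _encode(b)
    comparable = (ca < 4) & (cb < 4)
    m = int(comparable.sum())
    if m == 0:
        raise ValueError("no comparable (unambiguous) sites; p-distance undefined")
    return float(np.sum(ca[comparable] != cb[comparable])) / m


def _codes_matrix(sequences: dict[str, str]) -> tuple[list[str], np.ndarray]:
    labels = list(sequences)
    lengths = {len(s) for s in sequences.values()}
    if len(lengths) != 1:
        raise ValueError("alignment sequences must have equal length")
    codes = np.vstack([_encode(sequences[lab]) for lab in labels])
    return labels, codes


def _distances_from_codes(labels: list[str], codes: np.ndarray) -> DistanceMatrix:
    """All-pairs p-distances via one-hot inner products (fast, exact)."""
    n, L = codes.shape
    valid = (codes < 4).astype(np.float64)
    onehot = np.zeros((n, L, 4), dtype=np.float64)
    for a in range(4):
        onehot[:, :, a] = codes == a
    flat = onehot.reshape(n, L * 4)
    matches = flat @ flat.T
    comparable = valid @ valid.T
    bad = (comparable == 0) & ~np.eye(n, dtype=bool)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"no comparable sites for pair ({labels[i]!r}, {labels[j]!r})"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = 1.0 - matches / np.maximum(comparable, 1.0)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 1.0)
    return DistanceMatrix(labels, dist.astype(float))


def alignment_distances(sequences: dict[str, str]) -> DistanceMatrix:
    """Pairwise p-distance matrix for an aligned sequence set."""
    labels, codes = _codes_matrix(sequences)
    return _distances_from_codes(labels, codes)


def bootstrap_support(
    sequences: dict[str, str],
    n_replicates: int = 100,
    seed: int = 0,
):
    """NJ tree from aligned sequences with bootstrap branch supports.

    Returns (tree, n_skipped): the full-data NJ tree (zero-length internal
    branches collapsed into polytomies) whose internal nodes carry support
    labels in [0, 100], and the number of degenerate replicates skipped.
    Deterministic for a fixed seed.
    """
    if len(sequences) < 4:
        raise ValueError("bootstrap_support requires >= 4 sequences")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    labels, codes = _codes_matrix(sequences)
    full = nj_tree(_distances_from_codes(labels, codes))
    collapse_zero_branches(full)
    target = bipartitions(full)
    hits = {key: 0 for key in target}

    rng = derived_rng(seed, "bootstrap")
    L = codes.shape[1]
    skipped = 0
    completed = 0
    for _ in range(n_replicates):
        idx = rng.integers(0, L, size=L)
        sub = codes[:, idx]
        try:
            dm = _distances_from_codes(labels, sub)
        except ValueError as exc:
            skipped += 1
            logger.warning("bootstrap replicate skipped: %s", exc)
            continue
        rep = bipartitions(nj_tree(dm))
        completed += 1
        for key in hits:
            if key in rep:
                hits[key] += 1

    for key, node in target.items():
        support = 100.0 * hits[key] / completed if completed else 0.0
        node.label = f"{support:g}"
    if skipped:
        logger.warning("%d/%d bootstrap replicates skipped", skipped, n_replicates)
    return full, skipped


def population_assignment(tree, subpop_labels: dict[str, str]) -> pd.DataFrame:
    """Per-subpopulation monophyly report for an unrooted tree.

    A subpopulation is monophyletic when some bipartition separates exactly
    its leaf set (single-sample groups trivially are). Support is the branch
    label of that bipartition when present.
    """
    leaves = set()
    for node in tree.leaf_node_iter():
        leaves.add(node.taxon.label)
    missing = [lf for lf in leaves if lf not in subpop_labels]
    if missing:
        raise ValueError(f"leaves without subpopulation labels: {missing}")
    bips = bipartitions(tree)
    all_leaves = frozenset(leaves)
    rows = []
    for subpop in sorted(set(subpop_labels.values())):
        members = frozenset(
            lf for lf, sp in subpop_labels.items() if sp == subpop and lf in leaves
        )
        if len(members) <= 1:
            rows.append(
                {"subpop": subpop, "n": len(members), "monophyletic": True, "support": np.nan}
            )
            continue
        key = min(members, all_leaves - members, key=lambda s: (len(s), tuple(sorted(s))))
        node = bips.get(key)
        mono = node is not None and (
            frozenset(lf.taxon.label for lf in node.leaf_iter()) in (members, all_leaves - members)
        )
        support = np.nan
        if mono and node.label is not None:
            try:
                support = float(node.label)
            except ValueError:
                pass
        rows.append(
            {"subpop": subpop, "n": len(members), "monophyletic": bool(mono), "support": support}
        )
    return pd.DataFrame(rows)


def read_alignment(path) -> dict[str, str]:
    from Bio import SeqIO

    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise ValueError(f"no sequences found in {path}")
    return seqs


def pileup_from_sequence(seq: str, depth: int = 1) -> np.ndarray:
    """One-hot pileup for a sequence (testing/pipeline helper); non-ACGT
    positions get zero coverage."""
    codes = _encode(seq)
    L = len(codes)
    counts = np.zeros((L, 4), dtype=np.int64)
    ok = codes < 4
    counts[np.nonzero(ok)[0], codes[ok].astype(np.intp)] = depth
    return counts
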