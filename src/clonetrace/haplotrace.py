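"""Majority/minority (A/B) haplotype ancestry tracing for a clonal triploid.

At every biallelic heterozygous site of the triploid reference individual,
two of the three genome copies carry one allele (the majority, "A", expected
read fraction 2/3) and one copy carries the other (the minority, "B",
expected 1/3). Because the clonal genome is unrecombined, the A alleles
jointly spell out one parental haplotype and the B alleles the other.
Scoring each allele's presence or absence in every candidate parent-
population sample yields one binary matrix per haplotype; neighbor-joining
trees on row distances then place each parental haplotype inside the
population it came from.

Sites where read support cannot separate majority from minority (minor-of-
pair fraction inside the ambiguity band, default [0.45, 0.55]) are excluded,
since misassignment would mix the two haplotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype import Allelism, Call, GenotypeCalls
from .ploidy import PloidyParams, build_spectrum, classify_ploidy, _window_masses
from .simulate import ALPHABET, AlleleDepthProfile
from .trees import DistanceMatrix, nj_tree, patristic_distances

__all__ = [
    "ABAlleleSet",
    "PresenceMatrix",
    "DistanceMatrix",
    "identify_ab_alleles",
    "build_presence_matrix",
    "presence_distance",
    "nj_tree",
    "haplotype_trees",
    "nearest_leaf",
]

logger = logging.getLogger(__name__)


@dataclass
class ABAlleleSet:
    """Majority (A) and minority (B) alleles at the reference individual's
    biallelic heterozygous positions."""

    positions: np.ndarray  # 1-based, strictly increasing
    a_alleles: np.ndarray  # int8 codes
    b_alleles: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.positions) == len(self.a_alleles) == len(self.b_alleles)):
            raise ValueError("positions, a_alleles and b_alleles must align")
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing and unique")
        if np.any(self.a_alleles == self.b_alleles):
            raise ValueError("A and B alleles must differ at every entry")

    def __len__(self) -> int:
        return len(self.positions)

    def to_dataframe(self) -> pd.DataFrame:
        base = np.array(list(ALPHABET))
        return pd.DataFrame(
            {
                "position": self.positions,
                "A": base[self.a_alleles],
                "B": base[self.b_alleles],
            }
        )


@dataclass
class PresenceMatrix:
    """Samples x alleles binary presence matrix; NaN marks no-calls."""

    haplotype_label: str  # "A" or "B"
    samples: list[str]
    positions: np.ndarray
    cells: np.ndarray  # float: 1.0, 0.0 or NaN

    def __post_init__(self) -> None:
        if self.cells.shape != (len(self.samples), len(self.positions)):
            raise ValueError("cells must be samples x alleles")

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.cells, index=self.samples, columns=self.positions)
        return df

    def to_tsv(self, path) -> None:
        df = self.to_dataframe()
        out = df.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
        out.to_csv(path, sep="\t")


def identify_ab_alleles(
    reference_profile: AlleleDepthProfile,
    calls: GenotypeCalls,
    ploidy_params: PloidyParams | None = None,
    ambiguity_band: tuple[float, float] = (0.45, 0.55),
) -> ABAlleleSet:
    """Split the reference individual's het sites into A and B alleles.

    Refuses when the reference individual's spectrum classifies as diploid;
    with too few het sites for a confident ploidy call, it proceeds only if
    the spectrum's window masses are still triploid-shaped (M3 > M2).
    """
    ploidy_params = ploidy_params or PloidyParams()
    spectrum = build_spectrum(calls, ploidy_params.bin_width)
    pc = classify_ploidy(spectrum, ploidy_params)
    if pc.classification == "diploid":
        raise ValueError(
            f"reference individual {calls.sample_id!r} classifies as diploid "
            f"(modal peak {pc.modal_peak}); A/B haplotype decomposition requires "
            "a triploid reference"
        )
    if pc.classification == "indeterminate":
        m3, m2 = _window_masses(spectrum.frequencies, ploidy_params.window)
        if not (spectrum.n_het_sites > 0 and m3 > m2):
            raise ValueError(
                f"reference individual {calls.sample_id!r} has too few het sites "
                f"({spectrum.n_het_sites}) and no triploid-shaped spectrum"
            )
        logger.warning(
            "reference %s below the confident het-site floor (%d sites); "
            "proceeding on a triploid-shaped spectrum",
            calls.sample_id,
            spectrum.n_het_sites,
        )

    het = (
        (calls.call == Call.HET)
        & (calls.allelism == Allelism.BIALLELIC)
    )
    idx = np.nonzero(het)[0]
    rows = idx
    a_allele = calls.allele1[rows]  # allele1 = more-supported of the pair
    b_allele = calls.allele2[rows]
    # minority-of-pair support fraction; ambiguous sites excluded
    counts = reference_profile.counts[rows]
    a_c = counts[np.arange(len(rows)), a_allele.astype(np.intp)]
    b_c = counts[np.arange(len(rows)), b_allele.astype(np.intp)]
    pair_tot = a_c + b_c
    with np.errstate(invalid="ignore", divide="ignore"):
        minor_frac = np.where(pair_tot > 0, b_c / np.maximum(pair_tot, 1), np.nan)
    lo, hi = ambiguity_band
    keep = (pair_tot > 0) & ((minor_frac < lo) | (minor_frac > hi))
    return ABAlleleSet(
        positions=calls.positions[rows[keep]],
        a_alleles=a_allele[keep],
        b_alleles=b_allele[keep],
    )


def build_presence_matrix(
    ab: ABAlleleSet,
    cohort_calls: list[GenotypeCalls],
    haplotype_label: str,
) -> PresenceMatrix:
    """Score presence (1) / absence (0) of each A or B allele per sample.

    A cell is 1 iff the sample's called genotype at that position includes
    the designated allele (het or hom), 0 if called without it, NaN when the
    sample has no call (or no site) there.
    """
    if len(ab) == 0:
        raise ValueError("ABAlleleSet is empty")
    if haplotype_label not in ("A", "B"):
        raise ValueError(f"haplotype_label must be 'A' or 'B', got {haplotype_label!r}")
    target = ab.a_alleles if haplotype_label == "A" else ab.b_alleles
    samples = [c.sample_id for c in cohort_calls]
    cells = np.full((len(samples), len(ab)), np.nan)
    for s, calls in enumerate(cohort_calls):
        loc = np.searchsorted(calls.positions, ab.positions)
        ok = (loc < len(calls.positions)) & (
            calls.positions[np.minimum(loc, len(calls.positions) - 1)] == ab.positions
        )
        li = loc[ok]
        called = calls.call[li] != Call.NO_CALL
        present = (calls.allele1[li] == target[ok]) | (
            (calls.call[li] == Call.HET) & (calls.allele2[li] == target[ok])
        )
        row = np.full(len(ab), np.nan)
        vals = np.where(called, present.astype(float), np.nan)
        row[np.nonzero(ok)[0]] = vals
        cells[s] = row
    return PresenceMatrix(haplotype_label, samples, ab.positions.copy(), cells)


def presence_distance(matrix: PresenceMatrix, metric: str = "hamming") -> DistanceMatrix:
    """Pairwise row distances over jointly non-missing columns.

    ``hamming``: fraction of jointly scored columns where the rows differ.
    ``jaccard``: 1 - |both present| / |either present| (0 when neither row
    has any presence among jointly scored columns).
    """
    if metric not in ("hamming", "jaccard"):
        raise ValueError(f"unknown metric {metric!r}")
    X = matrix.cells
    n = len(matrix.samples)
    if n < 2:
        raise ValueError("presence_distance requires >= 2 samples")
    valid = ~np.isnan(X)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(
                    "no jointly scored alleles for pair "
                    f"({matrix.samples[i]!r}, {matrix.samples[j]!r}); "
                    "distance undefined"
                )
            xi, xj = X[i, both], X[j, both]
            if metric == "hamming":
                d = float(np.mean(xi != xj))
            else:
                union = float(np.sum((xi == 1) | (xj == 1)))
                inter = float(np.sum((xi == 1) & (xj == 1)))
                d = 0.0 if union == 0 else 1.0 - inter / union
            values[i, j] = values[j, i] = d
    return DistanceMatrix(list(matrix.samples), values)


def _with_pseudo_row(matrix: PresenceMatrix, pseudo_label: str) -> PresenceMatrix:
    """Append the reference haplotype's own all-present row."""
    row = np.ones((1, len(matrix.positions)))
    return PresenceMatrix(
        matrix.haplotype_label,
        list(matrix.samples) + [pseudo_label],
        matrix.positions,
        np.vstack([matrix.cells, row]),
    )


def haplotype_trees(
    ab: ABAlleleSet,
    cohort_calls: list[GenotypeCalls],
    reference_id: str = "founder",
    metric: str = "hamming",
):
    """Per-haplotype presence matrices, distances and NJ trees.

    The reference individual itself enters each tree as a pseudo-sample
    ("<id>-A" / "<id>-B") whose presence row is all ones for its own
    haplotype, mirroring per-allele haplotype-placement trees. Its raw
    diploid-model row is excluded.

    Returns a dict with keys "A" and "B", each holding
    (PresenceMatrix, DistanceMatrix, tree).
    """
    others = [c for c in cohort_calls if c.sample_id != reference_id]
    out = {}
    for label in ("A", "B"):
        pm = build_presence_matrix(ab, others, label)
        pm = _with_pseudo_row(pm, f"{reference_id}-{label}")
        dm = presence_distance(pm, metric=metric)
        out[label] = (pm, dm, nj_tree(dm))
    return out


def nearest_leaf(tree, query: str, exclude: set[str] | None = None) -> tuple[str, float]:
    """Nearest other leaf to ``query`` by patristic distance."""
    pd_matrix = patristic_distances(tree)
    exclude = set(exclude or ())
    qi = pd_matrix.labels.index(query)
    best, best_d = None, np.inf
    for k, label in enumerate(pd_matrix.labels):
        if label == query or label in exclude:
            continue
        if pd_matrix.values[qi, k] < best_d:
            best, best_d = label, pd_matrix.values[qi, k]
    if best is None:
        raise ValueError("no candidate leaves left after exclusions")
    return best, float(best_d)
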