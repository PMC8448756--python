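"""Per-site genotype calling from allele-depth profiles under a diploid model.

A deliberately simple threshold caller stands in for a full Bayesian variant
caller: a site is callable at depth >= ``min_depth``; it is heterozygous when
the second-best-supported allele's read fraction lies in
[``het_min``, 1 - ``het_min``]; homozygous when the top allele's fraction
exceeds 1 - ``het_min``. Triploid samples are intentionally genotyped under
this diploid model — their heterozygous alternative-allele fractions then
cluster at 1/3 and 2/3, which is exactly the signal the ploidy module reads.

Allelism classes: a site is *triallelic* when at least three alleles each
pass the per-allele support thresholds; *biallelic* when exactly two do, or
when a single supported allele differs from the reference (a homozygous
substitution is a biallelic SNP relative to the reference); otherwise
*other* (monomorphic reference).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import ALPHABET, AlleleDepthProfile

_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}


class Call(IntEnum):
    HOM_REF = 0
    HET = 1
    HOM_ALT = 2
    NO_CALL = 3


class Allelism(IntEnum):
    OTHER = 0
    BIALLELIC = 1
    TRIALLELIC = 2


@dataclass
class CallingParams:
    """Thresholds of the diploid caller (all config-exposed)."""

    min_depth: int = 10
    het_min: float = 0.10
    allele_support_min: float = 0.05
    min_reads: int = 3

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError(f"min_depth must be >= 1, got {self.min_depth}")
        if not 0 < self.het_min <= 0.5:
            raise ValueError(f"het_min must be in (0, 0.5], got {self.het_min}")
        if not 0 <= self.allele_support_min < 1:
            raise ValueError(
                f"allele_support_min must be in [0, 1), got {self.allele_support_min}"
            )
        if self.min_reads < 1:
            raise ValueError(f"min_reads must be >= 1, got {self.min_reads}")


@dataclass
class GenotypeCalls:
    """Vectorized table of per-site genotype calls for one sample.

    ``allele1``/``allele2`` hold the called allele pair (equal for homozygous
    calls); ``alt_fraction`` is non-reference reads / total depth, NaN for
    no-calls.
    """

    sample_id: str
    positions: np.ndarray
    ref: np.ndarray
    call: np.ndarray  # Call codes, int8
    allele1: np.ndarray
    allele2: np.ndarray
    alt_fraction: np.ndarray
    allelism: np.ndarray  # Allelism codes, int8
    depth: np.ndarray

    def __len__(self) -> int:
        return len(self.positions)

    def to_dataframe(self) -> pd.DataFrame:
        base = np.array(list(ALPHABET) + ["-"])  # code -1 renders as '-'
        return pd.DataFrame(
            {
                "position": self.positions,
                "ref": base[self.ref],
                "call": pd.Categorical.from_codes(
                    self.call, categories=[c.name.lower() for c in Call]
                ),
                "allele1": base[self.allele1],
                "allele2": base[self.allele2],
                "alt_fraction": self.alt_fraction,
                "allelism": pd.Categorical.from_codes(
                    self.allelism, categories=[a.name.lower() for a in Allelism]
                ),
                "depth": self.depth,
            }
        )

    def summary(self) -> dict[str, int]:
        return {c.name.lower(): int((self.call == c).sum()) for c in Call}


def call_genotypes(
    profile: AlleleDepthProfile, params: CallingParams | None = None
) -> GenotypeCalls:
    """Call genotypes and allelism classes for every site of one profile."""
    params = params or CallingParams()
    n = len(profile)
    counts = profile.counts
    if n == 0:
        empty = np.zeros(0, dtype=np.int8)
        return GenotypeCalls(
            profile.sample_id,
            profile.positions,
            profile.ref.astype(np.int8),
            empty,
            empty.copy(),
            empty.copy(),
            np.zeros(0),
            empty.copy(),
            np.zeros(0, dtype=np.int64),
        )

    depth = counts.sum(axis=1)
    ref = profile.ref.astype(np.intp)
    # rank alleles by read count, ties broken toward the lower allele index
    order = np.argsort(-counts, axis=1, kind="stable")
    top, second = order[:, 0], order[:, 1]
    rows = np.arange(n)
    top_c = counts[rows, top]
    sec_c = counts[rows, second]

    with np.errstate(divide="ignore", invalid="ignore"):
        safe_depth = np.where(depth > 0, depth, 1)
        top_f = top_c / safe_depth
        sec_f = sec_c / safe_depth

    callable_ = depth >= params.min_depth
    het = callable_ & (sec_f >= params.het_min) & (sec_f <= 1 - params.het_min)
    hom = callable_ & ~het & (top_f > 1 - params.het_min)

    call = np.full(n, Call.NO_CALL, dtype=np.int8)
    call[het] = Call.HET
    call[hom & (top == ref)] = Call.HOM_REF
    call[hom & (top != ref)] = Call.HOM_ALT

    allele1 = top.astype(np.int8)
    allele2 = np.where(het, second, top).astype(np.int8)
    no_call = call == Call.NO_CALL
    allele1[no_call] = -1
    allele2[no_call] = -1

    alt_fraction = np.full(n, np.nan)
    called = ~no_call
    ref_reads = counts[rows, ref]
    alt_fraction[called] = (depth[called] - ref_reads[called]) / depth[called]

    supported = (counts >= params.min_reads) & (
        counts / safe_depth[:, None] > params.allele_support_min
    )
    n_supported = supported.sum(axis=1)
    ref_supported = supported[rows, ref]
    allelism = np.full(n, Allelism.OTHER, dtype=np.int8)
    allelism[(n_supported == 2) | ((n_supported == 1) & ~ref_supported & (depth > 0))] = (
        Allelism.BIALLELIC
    )
    allelism[n_supported >= 3] = Allelism.TRIALLELIC

    return GenotypeCalls(
        sample_id=profile.sample_id,
        positions=profile.positions,
        ref=profile.ref.astype(np.int8),
        call=call,
        allele1=allele1,
        allele2=allele2,
        alt_fraction=alt_fraction,
        allelism=allelism,
        depth=depth,
    )


def count_homozygous_variants(calls: GenotypeCalls) -> int:
    """Number of biallelic homozygous-alternative calls (fixed differences
    between the sample and the reference)."""
    return int(((calls.call == Call.HOM_ALT) & (calls.allelism == Allelism.BIALLELIC)).sum())


# ---------------------------------------------------------------------------
# marker-amplicon polymorphism counting


@dataclass
class MarkerPanel:
    """Named reference amplicon sequences (CytB/Dnmt1/Cox1-style markers)."""

    markers: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.markers.items():
            if not seq:
                raise ValueError(f"marker {name!r} has an empty sequence")

    @classmethod
    def from_fasta(cls, path) -> "MarkerPanel":
        from Bio import SeqIO

        return cls({rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")})


_UNAMBIGUOUS = frozenset("ACGT")


def count_marker_polymorphisms(sample_seq: str, marker_ref: str) -> int:
    """Count substitutions between two pre-aligned sequences.

    Positions where either sequence carries a gap or an ambiguity code are
    excluded. Raises if lengths differ (an external alignment is required).
    """
    if len(sample_seq) != len(marker_ref):
        raise ValueError(
            "sequences must be pre-aligned to equal length "
            f"(got {len(sample_seq)} vs {len(marker_ref)})"
        )
    count = 0
    for a, b in zip(sample_seq.upper(), marker_ref.upper()):
        if a in _UNAMBIGUOUS and b in _UNAMBIGUOUS and a != b:
            count += 1
    return count


# ---------------------------------------------------------------------------
# IO: cohort VCF reading, per-sample genotype tables


def read_vcf(path) -> list[AlleleDepthProfile]:
    """Read a cohort VCF with AD-style per-allele depths into profiles.

    Expects single-nucleotide REF/ALT alleles; AD in REF-then-ALT order.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    positions: list[int] = []
    refs: list[int] = []
    per_sample_counts: list[list[np.ndarray]] = [[] for _ in samples]
    for variant in vcf:
        alleles = [variant.REF] + [a for a in variant.ALT if a != "."]
        idx = [_BASE_INDEX[a] for a in alleles]
        positions.append(variant.POS)
        refs.append(idx[0])
        ad = variant.format("AD")
        for s in range(len(samples)):
            row = np.zeros(4, dtype=np.int64)
            vals = np.asarray(ad[s]).ravel()[: len(idx)]
            vals = np.where(vals < 0, 0, vals)  # missing AD encoded negative
            row[idx] = vals
            per_sample_counts[s].append(row)
    pos_arr = np.asarray(positions, dtype=np.int64)
    ref_arr = np.asarray(refs, dtype=np.int8)
    return [
        AlleleDepthProfile(
            sample_id=samples[s],
            positions=pos_arr.copy(),
            ref=ref_arr.copy(),
            counts=np.vstack(per_sample_counts[s]) if positions else np.zeros((0, 4), dtype=np.int64),
        )
        for s in range(len(samples))
    ]


def write_genotypes_tsv(calls: GenotypeCalls, path) -> None:
    calls.to_dataframe().to_csv(path, sep="\t", index=False)


def read_genotypes_tsv(path, sample_id: str | None = None) -> GenotypeCalls:
    df = pd.read_csv(path, sep="\t")
    call_codes = {c.name.lower(): int(c) for c in Call}
    allelism_codes = {a.name.lower(): int(a) for a in Allelism}
    base_codes = dict(_BASE_INDEX)
    base_codes["-"] = -1
    return GenotypeCalls(
        sample_id=sample_id or Path(str(path)).stem,
        positions=df["position"].to_numpy(np.int64),
        ref=df["ref"].map(_BASE_INDEX).to_numpy(np.int8),
        call=df["call"].map(call_codes).to_numpy(np.int8),
        allele1=df["allele1"].map(base_codes).fillna(-1).to_numpy(np.int8),
        allele2=df["allele2"].map(base_codes).fillna(-1).to_numpy(np.int8),
        alt_fraction=df["alt_fraction"].to_numpy(float),
        allelism=df["allelism"].map(allelism_codes).to_numpy(np.int8),
        depth=df["depth"].to_numpy(np.int64),
    )
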