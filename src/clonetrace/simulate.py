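"""Synthetic cohorts for clonal-triploid origin tracing.

Generates a structured diploid population (several diverged subpopulations,
each with a small pool of ancestral haplotypes that samples copy from), one
clonal triploid *founder* with an AAB genotype whose A and B haplotypes both
derive from a designated source subpopulation, optional non-founder triploids
in the same subpopulation, Poisson-depth sequencing reads with per-base error,
and one mitochondrial genome per maternal lineage.

The reference genome is defined as the founder's majority (A) haplotype, so a
triploid genotyped under a diploid model shows heterozygous alternative-allele
fractions peaking at 1/3, while true diploids peak at 1/2.

Mutation model: infinite-sites-style substitutions on the 4-letter alphabet
(the target allele is drawn uniformly from the three non-current letters), a
single linkage group without recombination. Linkage between nearby sites is
induced by shared pool-haplotype ancestry. All randomness derives from one
master seed; per-sample streams are obtained by stable hashing of
(master seed, purpose, sample id) so results are independent of iteration
order.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass

import numpy as np

ALPHABET = "ACGT"
_ALPHA_ARR = np.array(list(ALPHABET))

#: subpopulation names used by default for a 4-subpop cohort; the last one
#: (the "Everglades" analog) is the default founder source.
DEFAULT_SUBPOP_NAMES = ("Suwannee", "StJohns", "Southwest", "Everglades")

FOUNDER_ID = "founder"


def derived_rng(seed: int, *tags) -> np.random.Generator:
    """Generator for a stream identified by (seed, *tags).

    Stable across runs and iteration order: string tags are folded in via
    CRC32 so a sample's stream depends only on its identifier.
    """
    entropy = [int(seed) & 0x7FFFFFFF]
    for tag in tags:
        entropy.append(zlib.crc32(str(tag).encode()))
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must be a probability in [0, 1], got {value!r}")


def _check_count(name: str, value: int, minimum: int = 0) -> None:
    if int(value) != value or value < minimum:
        raise ValueError(f"{name} must be an integer >= {minimum}, got {value!r}")


@dataclass
class SimConfig:
    """Parameters of the synthetic study design.

    Defaults emulate the study conditions: 4 diverged subpopulations, 28
    sampled diploid-looking individuals, one triploid AAB founder rooted in
    the last ("Everglades"-analog) subpopulation, and 2 non-founder triploids
    in that same subpopulation.
    """

    n_subpops: int = 4
    samples_per_subpop: tuple[int, ...] | None = None
    n_sites: int = 50_000
    genome_length: int = 5_000_000
    subpop_divergence: float = 0.02
    within_subpop_diversity: float = 0.005
    founder_subpop: int = 3
    founder_AB_divergence: float = 0.004
    n_triploid_samples: int = 2
    #: ancestral haplotypes per subpop pool. Small pools keep each pool
    #: haplotype's sampling frequency high enough that a realistic cohort
    #: contains carriers of the founder's source lineages, which is the
    #: premise of the ancestry-tracing design.
    pool_haplotypes: int = 3
    private_mutation_rate: float = 5e-4
    mito_length: int = 15_000
    mito_divergence: float = 0.02
    mito_lineage_divergence: float = 2e-3
    mito_private_rate: float = 2e-4
    read_depth_mean: float = 30.0
    base_error: float = 0.002
    seed: int = 0
    #: if set, the founder's B haplotype is drawn from this subpopulation's
    #: ancestor instead of ``founder_subpop`` (the hybrid-origin scenario).
    hybrid_B_subpop: int | None = None
    subpop_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        _check_count("n_subpops", self.n_subpops, 1)
        if self.samples_per_subpop is None:
            base, rem = divmod(28, self.n_subpops)
            self.samples_per_subpop = tuple(
                base + (1 if i < rem else 0) for i in range(self.n_subpops)
            )
        self.samples_per_subpop = tuple(int(c) for c in self.samples_per_subpop)
        if len(self.samples_per_subpop) != self.n_subpops:
            raise ValueError(
                "samples_per_subpop must have one entry per subpopulation "
                f"(got {len(self.samples_per_subpop)} for n_subpops={self.n_subpops})"
            )
        for c in self.samples_per_subpop:
            _check_count("samples_per_subpop entries", c, 0)
        if sum(self.samples_per_subpop) < 1:
            raise ValueError("samples_per_subpop must sum to at least 1")
        _check_count("n_sites", self.n_sites, 1)
        _check_count("genome_length", self.genome_length, 1)
        if self.n_sites > self.genome_length:
            raise ValueError("n_sites cannot exceed genome_length")
        for name in (
            "subpop_divergence",
            "within_subpop_diversity",
            "founder_AB_divergence",
            "private_mutation_rate",
            "mito_divergence",
            "mito_lineage_divergence",
            "mito_private_rate",
            "base_error",
        ):
            _check_prob(name, getattr(self, name))
        if not 0 <= self.founder_subpop < self.n_subpops:
            raise ValueError(
                f"founder_subpop must be in [0, {self.n_subpops}), got {self.founder_subpop}"
            )
        if self.hybrid_B_subpop is not None:
            if not 0 <= self.hybrid_B_subpop < self.n_subpops:
                raise ValueError(
                    f"hybrid_B_subpop must be in [0, {self.n_subpops}), "
                    f"got {self.hybrid_B_subpop}"
                )
        _check_count("n_triploid_samples", self.n_triploid_samples, 0)
        if self.n_triploid_samples > self.samples_per_subpop[self.founder_subpop]:
            raise ValueError(
                "n_triploid_samples exceeds the number of samples in founder_subpop"
            )
        _check_count("pool_haplotypes", self.pool_haplotypes, 2)
        _check_count("mito_length", self.mito_length, 1)
        if self.read_depth_mean < 0:
            raise ValueError(f"read_depth_mean must be >= 0, got {self.read_depth_mean}")
        if self.subpop_names is None:
            if self.n_subpops == len(DEFAULT_SUBPOP_NAMES):
                self.subpop_names = DEFAULT_SUBPOP_NAMES
            else:
                self.subpop_names = tuple(f"pop{i + 1}" for i in range(self.n_subpops))
        if len(self.subpop_names) != self.n_subpops:
            raise ValueError("subpop_names must have one entry per subpopulation")


@dataclass
class TrueGenome:
    """Ground-truth genome of one individual over the shared site index."""

    sample_id: str
    ploidy: int
    haplotypes: list[np.ndarray]  # ploidy arrays of int8 allele codes
    subpop: int
    maternal_lineage: int
    is_founder: bool = False

    def __post_init__(self) -> None:
        if self.ploidy not in (2, 3):
            raise ValueError(f"ploidy must be 2 or 3, got {self.ploidy}")
        if len(self.haplotypes) != self.ploidy:
            raise ValueError("number of haplotypes must equal ploidy")


@dataclass
class CohortTruth:
    """Full ground truth for a simulated cohort."""

    genomes: list[TrueGenome]  # founder first
    reference_alleles: np.ndarray  # int8, = founder A haplotype
    site_positions: np.ndarray  # 0-based bp, strictly increasing
    mito_sequences: list[np.ndarray]  # one int8 array per maternal lineage
    subpop_names: tuple[str, ...]
    config: SimConfig

    @property
    def founder(self) -> TrueGenome:
        return next(g for g in self.genomes if g.is_founder)

    @property
    def non_founders(self) -> list[TrueGenome]:
        return [g for g in self.genomes if not g.is_founder]

    def subpop_of(self, sample_id: str) -> str:
        for g in self.genomes:
            if g.sample_id == sample_id:
                return self.subpop_names[g.subpop]
        raise KeyError(sample_id)


@dataclass
class AlleleDepthProfile:
    """Per-sample, per-site read counts for each of the four alleles.

    ``positions`` are 1-based bp on the shared reference; ``ref`` holds the
    reference allele code at each site; ``counts`` is (n_sites, 4).
    """

    sample_id: str
    positions: np.ndarray
    ref: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.ref) or len(self.positions) != len(self.counts):
            raise ValueError("positions, ref and counts must have equal length")
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def __len__(self) -> int:
        return len(self.positions)


def _mutate(hap: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site with probability ``rate``; target allele uniform
    over the three non-current letters."""
    out = hap.astype(np.int8, copy=True)
    if rate <= 0:
        return out
    mask = rng.random(out.size) < rate
    k = int(mask.sum())
    if k:
        out[mask] = (out[mask] + rng.integers(1, 4, size=k)) % 4
    return out


def simulate_population(config: SimConfig) -> CohortTruth:
    """Generate ground-truth genomes and mitochondrial lineage sequences.

    The cohort holds ``sum(samples_per_subpop)`` non-founder genomes plus one
    triploid AAB founder; ``n_triploid_samples`` non-founders are triploid and
    belong to ``founder_subpop``. The reference equals the founder's A
    haplotype. Deterministic for a fixed ``config.seed``.
    """
    cfg = config
    rng = derived_rng(cfg.seed, "population")

    positions = np.sort(rng.choice(cfg.genome_length, size=cfg.n_sites, replace=False))
    root = rng.integers(0, 4, size=cfg.n_sites, dtype=np.int8)
    ancestors = [_mutate(root, cfg.subpop_divergence, rng) for _ in range(cfg.n_subpops)]

    # Founder haplotypes: each diverged from the source ancestor at rate d/2,
    # so P(A != B per site) = d - d^2/3 ~ founder_AB_divergence.
    half = cfg.founder_AB_divergence / 2.0
    hap_a = _mutate(ancestors[cfg.founder_subpop], half, rng)
    b_source = cfg.founder_subpop if cfg.hybrid_B_subpop is None else cfg.hybrid_B_subpop
    hap_b = _mutate(ancestors[b_source], half, rng)

    # Standing variation: each subpop has a pool of ancestral haplotypes that
    # sampled individuals copy (with private mutations). The founder's A and B
    # belong to their source subpops' pools, so their alleles segregate there.
    pools: list[list[np.ndarray]] = []
    for sp in range(cfg.n_subpops):
        pool: list[np.ndarray] = []
        if sp == cfg.founder_subpop:
            pool.append(hap_a)
        if sp == b_source:
            pool.append(hap_b)
        while len(pool) < cfg.pool_haplotypes:
            pool.append(_mutate(ancestors[sp], cfg.within_subpop_diversity / 2.0, rng))
        pools.append(pool[: cfg.pool_haplotypes])

    founder = TrueGenome(
        sample_id=FOUNDER_ID,
        ploidy=3,
        haplotypes=[hap_a, hap_a.copy(), hap_b],
        subpop=cfg.founder_subpop,
        maternal_lineage=0,
        is_founder=True,
    )

    genomes: list[TrueGenome] = [founder]
    lineage_subpop: list[int] = [cfg.founder_subpop]  # lineage 0 = founder's
    next_lineage = 1
    for sp in range(cfg.n_subpops):
        n_tri = cfg.n_triploid_samples if sp == cfg.founder_subpop else 0
        for k in range(cfg.samples_per_subpop[sp]):
            sid = f"{cfg.subpop_names[sp]}-{k + 1}"
            srng = derived_rng(cfg.seed, "genome", sid)
            pool = pools[sp]
            triploid = k < n_tri
            if triploid:
                i, j = srng.choice(len(pool), size=2, replace=False)
                aa = _mutate(pool[i], cfg.private_mutation_rate, srng)
                haps = [aa, aa.copy(), _mutate(pool[j], cfg.private_mutation_rate, srng)]
                # non-founder triploids share the founder's maternal lineage
                lineage = 0
                ploidy = 3
            else:
                draws = srng.integers(0, len(pool), size=2)
                haps = [
                    _mutate(pool[d], cfg.private_mutation_rate, srng) for d in draws
                ]
                lineage = next_lineage
                lineage_subpop.append(sp)
                next_lineage += 1
                ploidy = 2
            genomes.append(
                TrueGenome(
                    sample_id=sid,
                    ploidy=ploidy,
                    haplotypes=haps,
                    subpop=sp,
                    maternal_lineage=lineage,
                    is_founder=False,
                )
            )

    # Mitochondrial lineage sequences: root -> subpop ancestor -> lineage.
    mrng = derived_rng(cfg.seed, "mito")
    mito_root = mrng.integers(0, 4, size=cfg.mito_length, dtype=np.int8)
    mito_ancestors = [
        _mutate(mito_root, cfg.mito_divergence, mrng) for _ in range(cfg.n_subpops)
    ]
    mito_sequences = [
        _mutate(mito_ancestors[sp], cfg.mito_lineage_divergence, mrng)
        for sp in lineage_subpop
    ]

    return CohortTruth(
        genomes=genomes,
        reference_alleles=hap_a.copy(),
        site_positions=positions.astype(np.int64),
        mito_sequences=mito_sequences,
        subpop_names=cfg.subpop_names,
        config=cfg,
    )


def simulate_allele_depths(
    genome: TrueGenome,
    truth: CohortTruth,
    depth_mean: float,
    base_error: float,
    seed: int,
) -> AlleleDepthProfile:
    """Draw per-site read counts for one genome.

    Total depth per site is Poisson(``depth_mean``); each read picks one of
    the genome's haplotypes uniformly and is corrupted to a uniformly chosen
    different allele with probability ``base_error``. Deterministic for a
    fixed seed (stream keyed by the sample id).
    """
    if depth_mean < 0:
        raise ValueError(f"depth_mean must be >= 0, got {depth_mean}")
    _check_prob("base_error", base_error)
    rng = derived_rng(seed, "depths", genome.sample_id)
    n = len(truth.site_positions)
    counts = np.zeros((n, 4), dtype=np.int64)
    depth = rng.poisson(depth_mean, size=n)

    # uniform multinomial split of depth across haplotypes
    remaining = depth.copy()
    p = genome.ploidy
    rows = np.arange(n)
    for h in range(p):
        c = remaining if h == p - 1 else rng.binomial(remaining, 1.0 / (p - h))
        np.add.at(counts, (rows, genome.haplotypes[h].astype(np.intp)), c)
        remaining = remaining - c

    if base_error > 0:
        for a in range(4):
            err = rng.binomial(counts[:, a], base_error)
            if not err.any():
                continue
            counts[:, a] -= err
            others = [b for b in range(4) if b != a]
            e1 = rng.binomial(err, 1.0 / 3.0)
            e2 = rng.binomial(err - e1, 0.5)
            counts[:, others[0]] += e1
            counts[:, others[1]] += e2
            counts[:, others[2]] += err - e1 - e2

    return AlleleDepthProfile(
        sample_id=genome.sample_id,
        positions=truth.site_positions + 1,
        ref=truth.reference_alleles.copy(),
        counts=counts,
    )


def simulate_cohort_depths(truth: CohortTruth, config: SimConfig | None = None) -> list[AlleleDepthProfile]:
    """Allele-depth profiles for every genome in the cohort (founder first)."""
    cfg = config or truth.config
    return [
        simulate_allele_depths(g, truth, cfg.read_depth_mean, cfg.base_error, cfg.seed)
        for g in truth.genomes
    ]


def simulate_mito(truth: CohortTruth, config: SimConfig | None = None) -> dict[str, str]:
    """Per-sample mitochondrial sequences (pre-aligned, equal length).

    Each sample's sequence is its maternal-lineage sequence plus independent
    per-site private mutations at ``mito_private_rate``.
    """
    cfg = config or truth.config
    out: dict[str, str] = {}
    for g in truth.genomes:
        srng = derived_rng(cfg.seed, "mito-sample", g.sample_id)
        seq = _mutate(truth.mito_sequences[g.maternal_lineage], cfg.mito_private_rate, srng)
        out[g.sample_id] = "".join(_ALPHA_ARR[seq])
    return out


# ---------------------------------------------------------------------------
# external interfaces: minimal cohort VCF, multi-FASTA, truth JSON


def write_vcf(truth: CohortTruth, profiles: list[AlleleDepthProfile], path, contig: str = "sim1") -> None:
    """Write the cohort as a minimal multi-sample VCF with DP and AD fields.

    One row per simulated site (1-based positions); ALT lists every non-
    reference allele observed in any sample, AD follows REF-then-ALT order.
    """
    samples = [p.sample_id for p in profiles]
    n = len(truth.site_positions)
    all_counts = np.stack([p.counts for p in profiles])  # (n_samples, n, 4)
    ref = truth.reference_alleles
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig},length={truth.config.genome_length}>\n")
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Read depth per allele (ref first)">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for i in range(n):
            r = int(ref[i])
            observed = np.nonzero(all_counts[:, i, :].sum(axis=0) > 0)[0]
            alts = [a for a in observed if a != r]
            alt_str = ",".join(ALPHABET[a] for a in alts) if alts else "."
            order = [r] + alts
            fields = []
            for s in range(len(samples)):
                c = all_counts[s, i]
                ad = ",".join(str(int(c[a])) for a in order)
                fields.append(f"{int(c.sum())}:{ad}")
            fh.write(
                f"{contig}\t{int(truth.site_positions[i]) + 1}\t.\t{ALPHABET[r]}\t"
                f"{alt_str}\t.\tPASS\t.\tDP:AD\t" + "\t".join(fields) + "\n"
            )


def write_mito_fasta(sequences: dict[str, str], path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def write_truth(truth: CohortTruth, path) -> None:
    """Serialize cohort ground truth (sans haplotypes) as JSON."""
    payload = {
        "config": dataclasses.asdict(truth.config),
        "subpop_names": list(truth.subpop_names),
        "site_positions": truth.site_positions.tolist(),
        "reference_alleles": "".join(_ALPHA_ARR[truth.reference_alleles]),
        "samples": [
            {
                "sample_id": g.sample_id,
                "ploidy": g.ploidy,
                "subpop": truth.subpop_names[g.subpop],
                "maternal_lineage": g.maternal_lineage,
                "is_founder": g.is_founder,
            }
            for g in truth.genomes
        ],
        "mito_lineages": ["".join(_ALPHA_ARR[s]) for s in truth.mito_sequences],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
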