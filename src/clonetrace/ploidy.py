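"""Ploidy classification from heterozygous allele-frequency spectra.

A diploid genotyped under the diploid model shows heterozygous
alternative-allele read fractions distributed as Binomial(depth, 1/2)/depth,
peaking at 0.5. A triploid AAB genome genotyped the same way mixes
Binomial(depth, 1/3) and Binomial(depth, 2/3) fractions, peaking at 0.33
(and 0.67 when the reference carries the majority allele only at some
sites). Classification is deliberately bin-free: it compares the fraction of
het sites falling inside windows of half-width ``window`` around {1/3, 2/3}
(mass M3) versus around 1/2 (mass M2) and calls triploid iff M3 > M2. The
histogram (default bin width 0.02) is for reporting and display only, and
its highest bin's midpoint is the reported modal peak.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype import Allelism, Call, CallingParams, GenotypeCalls, call_genotypes
from .simulate import AlleleDepthProfile

logger = logging.getLogger(__name__)


@dataclass
class PloidyParams:
    bin_width: float = 0.02
    window: float = 0.08
    min_het_sites: int = 200

    def __post_init__(self) -> None:
        if not 0 < self.bin_width <= 0.5:
            raise ValueError(f"bin_width must be in (0, 0.5], got {self.bin_width}")
        if not 0 < self.window < 1 / 6:
            raise ValueError(
                f"window must be in (0, 1/6) so the mass windows do not overlap, "
                f"got {self.window}"
            )
        if self.min_het_sites < 0:
            raise ValueError(f"min_het_sites must be >= 0, got {self.min_het_sites}")


@dataclass
class AlleleFrequencySpectrum:
    """Alt-allele fractions of biallelic het calls, plus a display histogram."""

    sample_id: str
    frequencies: np.ndarray
    bin_edges: np.ndarray
    counts: np.ndarray

    @property
    def n_het_sites(self) -> int:
        return len(self.frequencies)

    @property
    def modal_peak(self) -> float | None:
        """Midpoint of the highest-count bin, rounded to 2 decimals."""
        if self.n_het_sites == 0:
            return None
        i = int(np.argmax(self.counts))
        return round(float((self.bin_edges[i] + self.bin_edges[i + 1]) / 2), 2)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start": self.bin_edges[:-1],
                "bin_end": self.bin_edges[1:],
                "count": self.counts,
            }
        )


@dataclass
class PloidyCall:
    sample_id: str
    classification: str  # diploid | triploid | indeterminate
    modal_peak: float | None
    n_het_sites: int
    triallelic_fraction: float
    m2: float = float("nan")
    m3: float = float("nan")


def build_spectrum(
    calls: GenotypeCalls, bin_width: float = 0.02, sample_id: str | None = None
) -> AlleleFrequencySpectrum:
    """Spectrum of alt-allele fractions over biallelic heterozygous calls.

    Only het calls whose called allele pair includes the reference allele
    contribute (their fraction is strictly inside (0, 1)); homozygous calls
    are discarded from the spectrum.
    """
    keep = (
        (calls.call == Call.HET)
        & (calls.allelism == Allelism.BIALLELIC)
        & ((calls.allele1 == calls.ref) | (calls.allele2 == calls.ref))
    )
    freqs = calls.alt_fraction[keep]
    freqs = freqs[(freqs > 0) & (freqs < 1)]
    n_bins = int(round(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(freqs, bins=edges)
    return AlleleFrequencySpectrum(
        sample_id=sample_id or calls.sample_id,
        frequencies=freqs,
        bin_edges=edges,
        counts=counts,
    )


def _window_masses(freqs: np.ndarray, w: float) -> tuple[float, float]:
    n = len(freqs)
    if n == 0:
        return float("nan"), float("nan")
    in3 = (np.abs(freqs - 1 / 3) <= w) | (np.abs(freqs - 2 / 3) <= w)
    in2 = np.abs(freqs - 0.5) <= w
    return float(in3.sum()) / n, float(in2.sum()) / n


def classify_ploidy(
    spectrum: AlleleFrequencySpectrum,
    params: PloidyParams | None = None,
    triallelic_frac: float = float("nan"),
) -> PloidyCall:
    """Classify a spectrum as diploid or triploid by window-mass comparison.

    Indeterminate when fewer than ``min_het_sites`` heterozygous sites are
    available (the masses are then noise-dominated).
    """
    params = params or PloidyParams()
    m3, m2 = _window_masses(spectrum.frequencies, params.window)
    if spectrum.n_het_sites < params.min_het_sites:
        classification = "indeterminate"
    else:
        classification = "triploid" if m3 > m2 else "diploid"
    return PloidyCall(
        sample_id=spectrum.sample_id,
        classification=classification,
        modal_peak=spectrum.modal_peak,
        n_het_sites=spectrum.n_het_sites,
        triallelic_fraction=triallelic_frac,
        m2=m2,
        m3=m3,
    )


def triallelic_fraction(calls: GenotypeCalls) -> float:
    """Triallelic / (biallelic + triallelic) among called variant sites."""
    called = calls.call != Call.NO_CALL
    tri = int(((calls.allelism == Allelism.TRIALLELIC) & called).sum())
    bi = int(((calls.allelism == Allelism.BIALLELIC) & called).sum())
    return tri / (tri + bi) if (tri + bi) else 0.0


def cohort_ploidy_screen(
    profiles: list[AlleleDepthProfile],
    calling_params: CallingParams | None = None,
    ploidy_params: PloidyParams | None = None,
) -> pd.DataFrame:
    """Ploidy screen across a cohort; per-sample failures do not abort.

    Returns one row per sample: classification, modal peak, het-site count
    and triallelic fraction.
    """
    if not profiles:
        raise ValueError("cohort_ploidy_screen requires at least one profile")
    ploidy_params = ploidy_params or PloidyParams()
    rows = []
    for profile in profiles:
        try:
            calls = call_genotypes(profile, calling_params)
            spectrum = build_spectrum(calls, ploidy_params.bin_width)
            pc = classify_ploidy(spectrum, ploidy_params, triallelic_fraction(calls))
        except Exception as exc:  # keep screening the rest of the cohort
            logger.warning("ploidy screen failed for %s: %s", profile.sample_id, exc)
            pc = PloidyCall(profile.sample_id, "indeterminate", None, 0, float("nan"))
        rows.append(
            {
                "sample": pc.sample_id,
                "classification": pc.classification,
                "modal_peak": pc.modal_peak,
                "n_het": pc.n_het_sites,
                "triallelic_fraction": pc.triallelic_fraction,
            }
        )
    return pd.DataFrame(rows)


def plot_spectrum(spectrum: AlleleFrequencySpectrum, path=None):
    """Histogram plot of the spectrum (display helper)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    widths = np.diff(spectrum.bin_edges)
    ax.bar(spectrum.bin_edges[:-1], spectrum.counts, width=widths, align="edge",
           color="#4878a8", edgecolor="none")
    ax.set_xlabel("alternative allele fraction")
    ax.set_ylabel("het sites")
    ax.set_title(spectrum.sample_id)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
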