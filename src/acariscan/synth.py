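"""Synthetic bioassay, chromatogram and linked strain-panel generators.

Everything downstream of the wet lab is testable against these
generators because they sample from exactly the statistical models the
analysis assumes: binomial mortality under a log-dose probit, two-allele
peak heights with truncated-Gaussian noise, and a monotone
genotype-to-phenotype link in which a resistance allele at frequency
``p`` shifts a strain's LD50 by the factor ``1 + (RRmax - 1) p``
(multiplicative per locus, additive across loci on the log10 scale).
All draws come from a single ``numpy`` Generator seeded in the config,
so identical configs give identical data.

Defaults mirror the vial-assay design this package targets: 17 mites
per vial, three replicate vials per dose, six doses spanning the
LD10-LD99 of the true line, a 12-strain panel with susceptible reference
strains at 0% allele frequency, and calibration standards at
0/10/30/50/70/90/100% resistant fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .bioassay import BioassayDataset, BioassayObservation
from .correlate import ResistancePanel
from .quantseq import (
    DEFAULT_STANDARD_FRACTIONS,
    CalibrationCurve,
    MutationDefinition,
    PeakSignal,
    QsCalibration,
    signal_ratio,
)

__all__ = [
    "ProbitTruth",
    "SimulationConfig",
    "ChromatogramConfig",
    "LinkedPanelConfig",
    "generic_mutation",
    "simulate_bioassay",
    "simulate_chromatogram",
    "simulate_calibration_standards",
    "simulate_linked_panel",
]

_Z = stats.norm.ppf


@dataclass(frozen=True)
class ProbitTruth:
    """True dose-response line of a simulated population."""

    ld50: float = 0.1
    slope: float = 2.0
    natural_response: float = 0.0

    def __post_init__(self) -> None:
        if self.ld50 <= 0 or self.slope <= 0 or not 0 <= self.natural_response < 1:
            raise ValueError("need ld50 > 0, slope > 0 and natural response in [0, 1)")

    @property
    def alpha(self) -> float:
        return -self.slope * np.log10(self.ld50)

    def ld(self, p: float) -> float:
        return float(10 ** ((_Z(p) - self.alpha) / self.slope))

    def mortality(self, dose) -> np.ndarray:
        c = self.natural_response
        return c + (1 - c) * stats.norm.cdf(self.alpha + self.slope * np.log10(np.asarray(dose, float)))

    def shifted(self, factor: float) -> "ProbitTruth":
        """Same line with LD50 multiplied by ``factor`` (resistance shift)."""
        return replace(self, ld50=self.ld50 * factor)


@dataclass
class SimulationConfig:
    """Bioassay simulation settings (one strain x acaricide assay)."""

    seed: int = 0
    probit: ProbitTruth = field(default_factory=ProbitTruth)
    doses: tuple[float, ...] | None = None  # default: 6 doses spanning LD10-LD99
    n_doses: int = 6
    n_per_vial: int = 17
    n_replicates: int = 3
    dose_unit: str = "ug/cm2"

    def dose_design(self) -> np.ndarray:
        if self.doses is not None:
            d = np.asarray(self.doses, dtype=float)
            if np.any(d <= 0):
                raise ValueError("design doses must be positive")
            return d
        lo, hi = self.probit.ld(0.10), self.probit.ld(0.99)
        return np.geomspace(lo, hi, self.n_doses)


def simulate_bioassay(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    strain: str = "sim",
    acaricide: str = "sim",
) -> BioassayDataset:
    """Draw one dose-mortality dataset: per vial,
    ``n_dead ~ Binomial(n, c + (1 - c) Phi(alpha + beta log10 d))``."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    ds = BioassayDataset(strain=strain, acaricide=acaricide, dose_unit=config.dose_unit)
    for dose in config.dose_design():
        pr = float(config.probit.mortality(dose))
        for rep in range(config.n_replicates):
            dead = int(rng.binomial(config.n_per_vial, pr))
            ds.append(BioassayObservation(float(dose), config.n_per_vial, dead, replicate=rep + 1))
    return ds


@dataclass
class ChromatogramConfig:
    """Two-allele peak-signal model at one SNP position.

    Heights of the two segregating peaks have means ``p * T`` and
    ``(1 - p) * T``; noise is Gaussian with sd ``noise_sd_frac * T``,
    truncated at zero (lognormal optional). The two non-segregating
    channels sit at a small baseline.
    """

    total_signal: float = 1000.0
    noise_sd_frac: float = 0.03
    baseline_frac: float = 0.02
    noise_model: str = "truncnorm"

    def __post_init__(self) -> None:
        if self.total_signal <= 0 or self.noise_sd_frac < 0 or self.baseline_frac < 0:
            raise ValueError("signal and noise parameters must be non-negative (signal > 0)")
        if self.noise_model not in ("truncnorm", "lognormal"):
            raise ValueError("noise_model must be 'truncnorm' or 'lognormal'")


def generic_mutation(name: str) -> MutationDefinition:
    """Placeholder A->G locus used when simulating a mutation known only
    by name (synthetic panels)."""
    return MutationDefinition(
        gene="sim",
        accession="synthetic",
        codon_position=1,
        wild_codon="ATT",
        mutant_codon="GTT",
        substituted_position_in_codon=1,
        wild_nt="A",
        mutant_nt="G",
        abbreviation=name,
    )


def _noisy(mean: float, sd: float, rng: np.random.Generator, model: str) -> float:
    if sd == 0:
        return float(mean)
    if model == "lognormal":
        if mean <= 0:
            return 0.0
        s2 = np.log1p((sd / mean) ** 2)
        return float(rng.lognormal(np.log(mean) - s2 / 2, np.sqrt(s2)))
    return float(max(rng.normal(mean, sd), 0.0))


def simulate_chromatogram(
    fraction: float,
    mutation: MutationDefinition | str,
    config: ChromatogramConfig | None = None,
    rng: np.random.Generator | None = None,
    sample: str = "sim",
) -> PeakSignal:
    """Draw the four-channel peak heights for a pool whose true
    resistant-allele fraction is ``fraction`` (0-1 scale)."""
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    config = config or ChromatogramConfig()
    rng = np.random.default_rng(0) if rng is None else rng
    mut = generic_mutation(mutation) if isinstance(mutation, str) else mutation
    T = config.total_signal
    sd = config.noise_sd_frac * T
    heights = {}
    for base in "ACGT":
        if base == mut.mutant_nt:
            mean = fraction * T
        elif base == mut.wild_nt:
            mean = (1 - fraction) * T
        else:
            mean = config.baseline_frac * T
        heights[base] = _noisy(mean, sd, rng, config.noise_model)
    return PeakSignal(sample=sample, mutation=mut, peak_heights=heights)


def simulate_calibration_standards(
    mutation: MutationDefinition | str,
    config: ChromatogramConfig | None = None,
    rng: np.random.Generator | None = None,
    fractions=DEFAULT_STANDARD_FRACTIONS,
    replicates: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate the known-mixture standard series; returns percent
    ``(fractions, signal_ratios)`` ready for :class:`QsCalibration`."""
    config = config or ChromatogramConfig()
    rng = np.random.default_rng(0) if rng is None else rng
    mut = generic_mutation(mutation) if isinstance(mutation, str) else mutation
    xs, ys = [], []
    for frac in fractions:
        for _ in range(replicates):
            sig = simulate_chromatogram(frac / 100.0, mut, config, rng)
            xs.append(frac)
            ys.append(signal_ratio(sig))
    return np.asarray(xs, float), np.asarray(ys, float)


@dataclass
class LinkedPanelConfig:
    """A strain panel with a known genotype-to-phenotype link.

    ``links`` maps each acaricide to the loci whose resistance alleles
    shift its LD50; a strain's LD50 is the susceptible LD50 times
    ``prod_l (1 + (RRmax_l - 1) p_l)`` over its linked loci. Mortality is
    scored at the diagnostic dose derived from the susceptible truth
    (2 x its LD90). Observed frequencies go through the full QS path:
    simulated standards -> calibration fit -> simulated sample
    chromatogram -> inverse prediction.
    """

    seed: int = 0
    strains: tuple[str, ...] = tuple(
        ["SUS-1", "SUS-2"] + [f"FIELD-{i}" for i in range(1, 9)] + ["RES-1", "RES-2"]
    )
    #: the 12 target-site mutations assayed by QS in the reference panel
    mutations: tuple[str, ...] = (
        "G228S", "G228A", "F439W", "F439Y", "L1022V", "A1376D",
        "F1704I", "G323D", "G326E", "I1017F", "G126S", "P262T",
    )
    acaricides: tuple[str, ...] = ("monocrotophos", "bifenthrin", "abamectin", "etoxazole")
    links: dict = field(default_factory=dict)  # acaricide -> list of mutation names
    rr_max: float = 50.0
    susceptible: ProbitTruth = field(default_factory=lambda: ProbitTruth(ld50=0.1, slope=2.0))
    frequencies: pd.DataFrame | None = None  # strains x mutations, 0-1 scale
    n_mites: int = 51  # 17 mites x 3 replicate vials at the diagnostic dose
    chromatogram: ChromatogramConfig = field(default_factory=ChromatogramConfig)
    standard_replicates: int = 1

    def resolved_links(self) -> dict:
        if self.links:
            return {a: list(m) for a, m in self.links.items()}
        defaults = {
            "monocrotophos": ["G228S"],
            "bifenthrin": ["L1022V", "A1376D"],
            "abamectin": ["G323D", "G326E"],
            "etoxazole": ["I1017F"],
        }
        out = {}
        for i, a in enumerate(self.acaricides):
            if a in defaults and all(m in self.mutations for m in defaults[a]):
                out[a] = defaults[a]
            else:
                out[a] = [self.mutations[i % len(self.mutations)]]
        return out

    def draw_frequencies(self, rng: np.random.Generator) -> pd.DataFrame:
        """True allele frequencies, 0-1. Strains named SUS-* are fixed at
        0 and RES-* at 1 so the panel spans the whole frequency range."""
        if self.frequencies is not None:
            return self.frequencies.copy()
        f = pd.DataFrame(
            rng.uniform(0, 1, size=(len(self.strains), len(self.mutations))),
            index=list(self.strains),
            columns=list(self.mutations),
        )
        for s in self.strains:
            if s.startswith("SUS"):
                f.loc[s] = 0.0
            elif s.startswith("RES"):
                f.loc[s] = 1.0
        return f


def simulate_linked_panel(
    config: LinkedPanelConfig,
    rng: np.random.Generator | None = None,
) -> tuple[ResistancePanel, dict]:
    """Generate a full panel (mortality % and observed QS frequency %)
    plus its ground truth.

    Returns ``(panel, truth)`` where ``truth`` holds the true frequency
    matrix (0-1), the per-strain true LD50s, the diagnostic doses used
    and the fitted calibration curves.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    links = config.resolved_links()
    freqs = config.draw_frequencies(rng)

    # phenotype layer: mortality at the susceptible-derived diagnostic dose
    dd = {a: 2.0 * config.susceptible.ld(0.9) for a in config.acaricides}
    ld50 = pd.DataFrame(index=freqs.index, columns=list(config.acaricides), dtype=float)
    mort = pd.DataFrame(index=freqs.index, columns=list(config.acaricides), dtype=float)
    for aca in config.acaricides:
        for strain in freqs.index:
            shift = 1.0
            for locus in links[aca]:
                shift *= 1.0 + (config.rr_max - 1.0) * float(freqs.loc[strain, locus])
            truth = config.susceptible.shifted(shift)
            ld50.loc[strain, aca] = truth.ld50
            pr = float(truth.mortality(dd[aca]))
            dead = int(rng.binomial(config.n_mites, pr))
            mort.loc[strain, aca] = 100.0 * dead / config.n_mites

    # genotype layer: QS pipeline per mutation, names resolved against the
    # packaged target-site panel so peak tables use the real channels
    from .io import load_mutation_panel, panel_by_abbreviation

    lookup = panel_by_abbreviation(load_mutation_panel())
    curves: dict[str, CalibrationCurve] = {}
    obs_freq = pd.DataFrame(index=freqs.index, columns=list(config.mutations), dtype=float)
    std_rows, peak_rows = [], []
    for m in config.mutations:
        mut = lookup.get(m) or generic_mutation(m)
        xs, ys = simulate_calibration_standards(
            mut, config.chromatogram, rng, replicates=config.standard_replicates
        )
        std_rows.extend(
            {"mutation": m, "resistant_fraction": x, "signal_ratio": y} for x, y in zip(xs, ys)
        )
        curves[m] = QsCalibration(xs, ys, mutation=mut).fit()
        for strain in freqs.index:
            sig = simulate_chromatogram(float(freqs.loc[strain, m]), mut, config.chromatogram, rng, sample=strain)
            peak_rows.append(
                {"sample": strain, "mutation": m}
                | {f"height_{b}": sig.peak_heights.get(b, 0.0) for b in "ACGT"}
            )
            obs_freq.loc[strain, m] = curves[m].predict(signal_ratio(sig)).frequency

    panel = ResistancePanel(mortality=mort, frequency=obs_freq)
    truth = {
        "frequencies": freqs,
        "ld50": ld50,
        "diagnostic_dose": dd,
        "curves": curves,
        "links": links,
        "standards": pd.DataFrame(std_rows),
        "peaks": pd.DataFrame(peak_rows),
    }
    return panel, truth
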