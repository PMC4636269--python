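"""Quantitative sequencing (QS): pooled allele-frequency estimation from
Sanger chromatogram peak-height ratios.

At a biallelic SNP position the relative height of the mutant nucleotide
peak in a pooled-template chromatogram tracks the resistant-allele
fraction of the pool. A calibration line is fitted on standards of known
resistant:susceptible mixing ratio (signal ratio regressed on true
fraction, both on the 0-100% scale); population samples are then read
off by inverse prediction. Detection limits bound the frequency range
over which the 95% inverse-prediction interval separates from 0% and
100%: outside them an estimate is censored, not quantified.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "MutationDefinition",
    "PeakSignal",
    "CalibrationStandard",
    "QsCalibration",
    "CalibrationCurve",
    "AlleleFrequencyEstimate",
    "signal_ratio",
    "fit_calibration",
    "predict_frequency",
    "batch_panel",
    "read_ab1_peaks",
]

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")

_AA3TO1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C", "Gln": "Q",
    "Glu": "E", "Gly": "G", "His": "H", "Ile": "I", "Leu": "L", "Lys": "K",
    "Met": "M", "Phe": "F", "Pro": "P", "Ser": "S", "Thr": "T", "Trp": "W",
    "Tyr": "Y", "Val": "V",
}


def substitution_class(wild_nt: str, mutant_nt: str) -> str:
    """Classify a point substitution as transition (purine<->purine or
    pyrimidine<->pyrimidine) or transversion."""
    w, m = wild_nt.upper(), mutant_nt.upper()
    if w == m or {w, m} - (_PURINES | _PYRIMIDINES):
        raise ValueError(f"not a substitution: {wild_nt}->{mutant_nt}")
    same = ({w, m} <= _PURINES) or ({w, m} <= _PYRIMIDINES)
    return "transition" if same else "transversion"


@dataclass(frozen=True)
class MutationDefinition:
    """One target-site resistance mutation of the monitoring panel.

    ``wild_codon`` and ``mutant_codon`` must differ at
    ``substituted_position_in_codon`` (1-based); ``wild_nt``/``mutant_nt``
    are the nucleotides segregating at that position, which are the two
    chromatogram peaks QS compares. ``abbreviation`` is the usual
    wild-AA/position/mutant-AA shorthand (e.g. ``G228S``).
    """

    gene: str
    accession: str
    codon_position: int
    wild_codon: str
    mutant_codon: str
    substituted_position_in_codon: int
    wild_nt: str
    mutant_nt: str
    abbreviation: str
    acaricide_class: str = ""
    target_protein: str = ""
    genetic_code: int = 1  # NCBI table; 5 (invertebrate mito) for cytochrome b

    def __post_init__(self) -> None:
        wc, mc = self.wild_codon.upper(), self.mutant_codon.upper()
        if len(wc) != 3 or len(mc) != 3:
            raise ValueError(f"{self.abbreviation}: codons must be 3 nt, got {wc}/{mc}")
        i = self.substituted_position_in_codon
        if not 1 <= i <= 3:
            raise ValueError(f"{self.abbreviation}: substituted position must be 1-3")
        if wc[i - 1] != self.wild_nt.upper() or mc[i - 1] != self.mutant_nt.upper():
            raise ValueError(
                f"{self.abbreviation}: wild/mutant nucleotides {self.wild_nt}->{self.mutant_nt} "
                f"do not match codons {wc}->{mc} at position {i}"
            )
        if wc[i - 1] == mc[i - 1]:
            raise ValueError(f"{self.abbreviation}: codons agree at the substituted position")
        diff = [k for k in range(3) if wc[k] != mc[k]]
        if i - 1 not in diff:
            raise ValueError(f"{self.abbreviation}: substituted position not among differences")

    @property
    def substitution_class(self) -> str:
        return substitution_class(self.wild_nt, self.mutant_nt)

    @property
    def wild_aa(self) -> str:
        return _translate(self.wild_codon, self.genetic_code)

    @property
    def mutant_aa(self) -> str:
        return _translate(self.mutant_codon, self.genetic_code)

    def check_abbreviation(self) -> None:
        """Verify the shorthand encodes wild AA, codon position, mutant AA."""
        expect = f"{self.wild_aa}{self.codon_position}{self.mutant_aa}"
        if self.abbreviation != expect:
            raise ValueError(
                f"abbreviation {self.abbreviation!r} does not encode "
                f"{self.wild_codon}->{self.mutant_codon} at codon {self.codon_position} "
                f"(expected {expect!r})"
            )

    def __str__(self) -> str:
        return f"{self.gene}:{self.abbreviation}"


def _translate(codon: str, table: int = 1) -> str:
    from Bio.Seq import Seq

    return str(Seq(codon.upper()).translate(table=table))


@dataclass
class PeakSignal:
    """Four-channel peak heights at one mutation position for one sample."""

    sample: str
    mutation: MutationDefinition | str
    peak_heights: dict[str, float]

    def __post_init__(self) -> None:
        self.peak_heights = {k.upper(): float(v) for k, v in self.peak_heights.items()}
        if any(v < 0 for v in self.peak_heights.values()):
            raise ValueError(f"{self.sample}: peak heights must be >= 0")
        if self.peak_heights and all(v == 0 for v in self.peak_heights.values()):
            raise ValueError(f"{self.sample}: all peak heights are zero")

    @property
    def mutation_name(self) -> str:
        return self.mutation if isinstance(self.mutation, str) else self.mutation.abbreviation


class UnquantifiableSignalError(ValueError):
    """Both segregating peaks are zero: no signal ratio can be formed."""


def signal_ratio(peaks: PeakSignal, mutation: MutationDefinition | None = None) -> float:
    """Resistant-nucleotide signal ratio, percent.

    ``100 * H_mut / (H_mut + H_wild)`` using only the two nucleotides
    segregating at the substituted position; background peaks of the
    other two channels are ignored. Scale-invariant in the overall trace
    intensity.
    """
    mut = mutation if mutation is not None else peaks.mutation
    if isinstance(mut, str) or mut is None:
        raise TypeError("a MutationDefinition is required to pick the segregating peaks")
    h_wild = peaks.peak_heights.get(mut.wild_nt.upper(), 0.0)
    h_mut = peaks.peak_heights.get(mut.mutant_nt.upper(), 0.0)
    if h_wild + h_mut <= 0:
        raise UnquantifiableSignalError(
            f"{peaks.sample}/{mut.abbreviation}: both segregating peaks are zero"
        )
    return 100.0 * h_mut / (h_mut + h_wild)


@dataclass(frozen=True)
class CalibrationStandard:
    """One known-mixture standard: true resistant fraction vs measured ratio (%)."""

    resistant_fraction: float
    signal_ratio: float

    def __post_init__(self) -> None:
        if not 0 <= self.resistant_fraction <= 100:
            raise ValueError("resistant_fraction must lie in [0, 100] %")
        if self.signal_ratio < 0:
            raise ValueError("signal_ratio must be >= 0")


#: default standard series: resistant:susceptible molar ratios
#: 0:10, 1:9, 3:7, 5:5, 7:3, 9:1, 10:0  ->  percent resistant
DEFAULT_STANDARD_FRACTIONS = (0.0, 10.0, 30.0, 50.0, 70.0, 90.0, 100.0)


class QsCalibration:
    """Calibration model for one mutation: signal ratio vs known fraction.

    Classical (forward) calibration: ordinary least squares of the
    measured signal ratio y on the true resistant fraction x, both in
    percent; population frequencies are recovered by inverting the line.
    The alternative ``direction="inverse"`` regresses x on y and
    predicts directly.

    Parameters
    ----------
    fractions, ratios : array_like
        Standard series, percent scales.
    mutation : MutationDefinition or str, optional
        Which mutation the curve belongs to.
    """

    def __init__(self, fractions, ratios, mutation: MutationDefinition | str | None = None):
        x = np.asarray(fractions, dtype=float)
        y = np.asarray(ratios, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("fractions and ratios must be equal-length 1-d arrays")
        if len(np.unique(x)) < 2:
            raise np.linalg.LinAlgError("calibration design is rank deficient: all fractions equal")
        if len(np.unique(x)) < 5:
            warnings.warn(
                "fewer than 5 distinct standard fractions; detection limits will be unstable",
                UserWarning,
                stacklevel=2,
            )
        self.x = x
        self.y = y
        self.mutation = mutation

    @classmethod
    def from_standards(cls, standards, mutation=None) -> "QsCalibration":
        xs = [s.resistant_fraction for s in standards]
        ys = [s.signal_ratio for s in standards]
        return cls(xs, ys, mutation=mutation)

    def fit(
        self,
        dl_convention: str = "prediction-band",
        confidence: float = 0.95,
        direction: str = "classical",
    ) -> "CalibrationCurve":
        import statsmodels.api as sm

        if direction not in ("classical", "inverse"):
            raise ValueError("direction must be 'classical' or 'inverse'")
        x, y = (self.x, self.y) if direction == "classical" else (self.y, self.x)
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        intercept, slope = float(ols.params[0]), float(ols.params[1])
        if abs(slope) < 1e-10:
            raise ValueError("non-informative calibration: fitted slope is ~0")
        n = len(x)
        resid_sd = float(np.sqrt(ols.mse_resid)) if n > 2 else 0.0
        return CalibrationCurve(
            mutation=self.mutation,
            slope=slope,
            intercept=intercept,
            r2=float(ols.rsquared),
            residual_sd=resid_sd,
            n_points=n,
            x_mean=float(np.mean(x)),
            sxx=float(np.sum((x - np.mean(x)) ** 2)),
            direction=direction,
            dl_convention=dl_convention,
            confidence=confidence,
        )


@dataclass
class CalibrationCurve:
    """Fitted QS calibration line with 95% detection limits.

    For the default classical direction the line is
    ``ratio = slope * fraction + intercept`` and inverse prediction gives
    ``fraction = (ratio - intercept) / slope``. ``lower_dl``/``upper_dl``
    are the frequencies at which the inverse-prediction interval first
    separates from 0% and 100%; estimates outside them carry a censoring
    status rather than a quantified value.
    """

    mutation: MutationDefinition | str | None
    slope: float
    intercept: float
    r2: float
    residual_sd: float
    n_points: int
    x_mean: float
    sxx: float
    direction: str = "classical"
    dl_convention: str = "prediction-band"
    confidence: float = 0.95
    lower_dl: float = field(init=False)
    upper_dl: float = field(init=False)

    def __post_init__(self) -> None:
        self.lower_dl, self.upper_dl = self._detection_limits()

    @property
    def mutation_name(self) -> str:
        if self.mutation is None:
            return ""
        return self.mutation if isinstance(self.mutation, str) else self.mutation.abbreviation

    # -- internal geometry ----------------------------------------------
    def _t(self) -> float:
        df = self.n_points - 2
        if df <= 0:
            return float("inf") if self.residual_sd > 0 else 0.0
        return float(stats.t.ppf(1 - (1 - self.confidence) / 2, df))

    def _halfwidth_freq(self, frequency: float) -> float:
        """Half-width (in % frequency) of the inverse-prediction interval
        for a single new measurement whose true frequency is ``frequency``."""
        if self.residual_sd == 0:
            return 0.0
        t = self._t()
        if self.direction == "classical":
            x = frequency
            w = self.residual_sd * math.sqrt(1 + 1 / self.n_points + (x - self.x_mean) ** 2 / self.sxx)
            return t * w / abs(self.slope)
        # inverse direction: x axis is the ratio; map frequency to ratio
        x = (frequency - self.intercept) / self.slope
        w = self.residual_sd * math.sqrt(1 + 1 / self.n_points + (x - self.x_mean) ** 2 / self.sxx)
        return t * w

    def _detection_limits(self) -> tuple[float, float]:
        if self.residual_sd == 0:
            return 0.0, 100.0
        if self.dl_convention == "prediction-band":
            lo = self._solve_crossing(lambda f: f - self._halfwidth_freq(f), 0.0)
            hi = self._solve_crossing(lambda f: f + self._halfwidth_freq(f) - 100.0, 100.0)
        elif self.dl_convention == "width-at-bound":
            lo = min(self._halfwidth_freq(0.0), 100.0)
            hi = max(100.0 - self._halfwidth_freq(100.0), 0.0)
        else:
            raise ValueError(f"unknown dl_convention {self.dl_convention!r}")
        if lo >= hi:
            warnings.warn(
                "detection limits collapsed: calibration noise leaves no quantifiable range",
                UserWarning,
                stacklevel=2,
            )
            lo, hi = min(lo, 100.0), max(hi, 0.0)
        return lo, hi

    def _solve_crossing(self, f, bound: float) -> float:
        """Root of f on [0, 100]; f(lower bound side) < 0 < f(other side)."""
        lo_v, hi_v = f(0.0), f(100.0)
        if lo_v >= 0:
            return 0.0 if bound == 0.0 else 0.0
        if hi_v <= 0:
            return 100.0
        return float(optimize.brentq(f, 0.0, 100.0, xtol=1e-9))

    # -- prediction ------------------------------------------------------
    def predict(self, ratio: float, clip: bool = True) -> "AlleleFrequencyEstimate":
        """Inverse-predict the resistant-allele frequency for one measured
        signal ratio (percent), with a 95% interval and censoring status."""
        if self.direction == "classical":
            point = (ratio - self.intercept) / self.slope
        else:
            point = self.slope * ratio + self.intercept
        half = self._halfwidth_freq(min(max(point, 0.0), 100.0))
        lo, hi = point - half, point + half
        if point < self.lower_dl:
            status = "below_detection"
        elif point > self.upper_dl:
            status = "above_detection"
        else:
            status = "quantified"
        if clip:
            point = min(max(point, 0.0), 100.0)
            lo, hi = min(max(lo, 0.0), 100.0), min(max(hi, 0.0), 100.0)
        return AlleleFrequencyEstimate(
            sample="", mutation=self.mutation, frequency=point, ci95=(lo, hi), status=status
        )

    def summary(self) -> str:
        eqn = (
            f"ratio = {self.slope:.4f} x fraction + {self.intercept:.4f}"
            if self.direction == "classical"
            else f"fraction = {self.slope:.4f} x ratio + {self.intercept:.4f}"
        )
        return "\n".join(
            [
                f"QS calibration: {self.mutation_name or '-'}",
                "=" * 50,
                eqn,
                f"r2 = {self.r2:.4f}   residual sd = {self.residual_sd:.3f} %"
                f"   n = {self.n_points}",
                f"detection limits ({100 * self.confidence:.0f}%): "
                f"{self.lower_dl:.1f} - {self.upper_dl:.1f} %",
            ]
        )

    def to_dict(self) -> dict:
        return {
            "mutation": self.mutation_name,
            "slope": self.slope,
            "intercept": self.intercept,
            "r2": self.r2,
            "residual_sd": self.residual_sd,
            "n_points": self.n_points,
            "x_mean": self.x_mean,
            "sxx": self.sxx,
            "direction": self.direction,
            "dl_convention": self.dl_convention,
            "confidence": self.confidence,
            "lower_dl": self.lower_dl,
            "upper_dl": self.upper_dl,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationCurve":
        d = {k: v for k, v in d.items() if k not in ("lower_dl", "upper_dl")}
        return cls(**d)


@dataclass
class AlleleFrequencyEstimate:
    """Resistant-allele frequency of one pooled sample at one mutation,
    percent scale, with inverse-prediction interval and censoring status."""

    sample: str
    mutation: MutationDefinition | str | None
    frequency: float
    ci95: tuple[float, float]
    status: str = "quantified"

    def __post_init__(self) -> None:
        if self.status not in ("quantified", "below_detection", "above_detection"):
            raise ValueError(f"unknown status {self.status!r}")


# ---------------------------------------------------------------------------
# functional surface


def fit_calibration(standards, mutation=None, **fit_kw) -> CalibrationCurve:
    """OLS calibration from ``CalibrationStandard`` records (or a
    ``(fractions, ratios)`` pair) for one mutation."""
    if isinstance(standards, tuple) and len(standards) == 2:
        model = QsCalibration(standards[0], standards[1], mutation=mutation)
    else:
        model = QsCalibration.from_standards(standards, mutation=mutation)
    return model.fit(**fit_kw)


def predict_frequency(ratio: float, curve: CalibrationCurve, sample: str = "") -> AlleleFrequencyEstimate:
    """Inverse-predict one sample's resistant-allele frequency from its ratio."""
    est = curve.predict(ratio)
    est.sample = sample
    return est


def batch_panel(
    samples: list[PeakSignal],
    curves: dict[str, CalibrationCurve],
) -> pd.DataFrame:
    """Strains x mutations frequency matrix (percent) from peak signals.

    Cells without an assay, without a calibration curve, or with an
    unquantifiable signal are NaN (serialised as 'nd'). Never fails on a
    single bad cell.
    """
    strains = list(dict.fromkeys(s.sample for s in samples))
    mutations = list(dict.fromkeys(s.mutation_name for s in samples))
    mat = pd.DataFrame(np.nan, index=strains, columns=mutations, dtype=float)
    for sig in samples:
        name = sig.mutation_name
        curve = curves.get(name)
        if curve is None:
            warnings.warn(f"no calibration curve for {name}; cell left nd", UserWarning, stacklevel=2)
            continue
        mut = sig.mutation if not isinstance(sig.mutation, str) else curve.mutation
        try:
            ratio = signal_ratio(sig, mut if isinstance(mut, MutationDefinition) else None)
        except (UnquantifiableSignalError, TypeError) as exc:
            warnings.warn(str(exc), UserWarning, stacklevel=2)
            continue
        mat.loc[sig.sample, name] = curve.predict(ratio).frequency
    return mat


def read_ab1_peaks(path, peak_index: int, sample: str | None = None) -> dict[str, float]:
    """Extract the four channel intensities at one called-base position of
    an AB1/ABIF trace.

    ``peak_index`` is the 0-based index of the called base whose position
    (from the PLOC record) is looked up; heights are read from the
    analysed DATA9-12 channels in the filter-wheel order (FWO) recorded in
    the file. No alignment is attempted: the caller supplies the index of
    the substituted position.
    """
    from Bio import SeqIO

    rec = SeqIO.read(str(path), "abi")
    raw = rec.annotations["abif_raw"]
    order = raw.get("FWO_1", b"GATC")
    if isinstance(order, bytes):
        order = order.decode()
    ploc = raw.get("PLOC2", raw.get("PLOC1"))
    if ploc is None:
        raise ValueError(f"{path}: no peak-location (PLOC) record in trace")
    if not 0 <= peak_index < len(ploc):
        raise IndexError(f"peak_index {peak_index} outside 0..{len(ploc) - 1}")
    pos = ploc[peak_index]
    heights = {}
    for i, base in enumerate(order):
        channel = raw[f"DATA{9 + i}"]
        heights[base.upper()] = float(channel[pos])
    return heights
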