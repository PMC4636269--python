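"""Readers, writers, the packaged mutation panel and the pipeline runner.

Tabular conventions: CSV inputs are UTF-8 with a decimal point; readers
address columns by name so column order never matters; writers emit a
fixed column order so repeated runs are byte-identical. Matrix outputs
use the literal ``nd`` for not-determined cells and serialise
mortalities and frequencies on the 0-100 percent scale.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .bioassay import BioassayDataset, BioassayObservation
from .correlate import ResistancePanel, correlation_matrix, render_heatmap
from .probit import NonIdentifiableFitError, ProbitNotDetermined, ProbitResults, fit_probit
from .quantseq import (
    CalibrationCurve,
    MutationDefinition,
    PeakSignal,
    QsCalibration,
    signal_ratio,
)

__all__ = [
    "BIOASSAY_COLUMNS",
    "RowError",
    "RunConfig",
    "ReportBundle",
    "load_mutation_panel",
    "read_bioassay_csv",
    "write_bioassay_csv",
    "read_peak_table_csv",
    "read_calibration_csv",
    "write_curves_json",
    "read_curves_json",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_probit_report",
    "run_pipeline",
]

ND = "nd"
BIOASSAY_COLUMNS = [
    "strain",
    "acaricide",
    "dose",
    "dose_unit",
    "n_treated",
    "n_dead",
    "exposure_h",
    "replicate",
]
_REQUIRED = ("strain", "acaricide", "dose", "n_treated", "n_dead")


@dataclass(frozen=True)
class RowError:
    """A malformed input row, reported with its 1-based file line number."""

    line: int
    message: str

    def __str__(self) -> str:
        return f"line {self.line}: {self.message}"


# ---------------------------------------------------------------------------
# mutation panel


def load_mutation_panel(path=None) -> list[MutationDefinition]:
    """Load a mutation-panel CSV (the packaged 18-mutation default when
    ``path`` is None), running codon/nucleotide/class consistency checks
    on every row; a failing row is named in the error."""
    if path is None:
        src = resources.files("acariscan").joinpath("data/mutation_panel.csv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    panel = []
    for i, row in df.iterrows():
        label = row.get("abbreviation", f"row {i + 2}")
        try:
            mut = MutationDefinition(
                gene=str(row["gene"]),
                accession=str(row["accession"]),
                codon_position=int(row["codon_position"]),
                wild_codon=str(row["wild_codon"]),
                mutant_codon=str(row["mutant_codon"]),
                substituted_position_in_codon=int(row["substituted_position_in_codon"]),
                wild_nt=str(row["wild_nt"]),
                mutant_nt=str(row["mutant_nt"]),
                abbreviation=str(row["abbreviation"]),
                acaricide_class=str(row.get("acaricide_class", "")),
                target_protein=str(row.get("target_protein", "")),
                genetic_code=int(row.get("genetic_code", 1)),
            )
            mut.check_abbreviation()
            declared = str(row.get("substitution_class", "")).lower()
            if declared and declared != mut.substitution_class:
                raise ValueError(
                    f"declared class {declared!r} does not match "
                    f"{mut.wild_nt}->{mut.mutant_nt} ({mut.substitution_class})"
                )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"mutation panel row {label} (file line {i + 2}): {exc}") from exc
        panel.append(mut)
    return panel


def panel_by_abbreviation(panel: list[MutationDefinition]) -> dict[str, MutationDefinition]:
    return {m.abbreviation: m for m in panel}


# ---------------------------------------------------------------------------
# bioassay tables


def read_bioassay_csv(path) -> tuple[list[BioassayDataset], list[RowError]]:
    """Read a dose-mortality CSV, grouping rows by strain x acaricide.

    Malformed rows are skipped and reported (with file line numbers);
    a missing required column raises immediately.
    """
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    datasets: dict[tuple[str, str], BioassayDataset] = {}
    errors: list[RowError] = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            obs = BioassayObservation(
                dose=float(row["dose"]),
                n_treated=int(row["n_treated"]),
                n_dead=int(row["n_dead"]),
                exposure_h=float(row["exposure_h"]) if pd.notna(row.get("exposure_h")) else 8.0,
                replicate=int(row["replicate"]) if pd.notna(row.get("replicate")) else None,
            )
        except (TypeError, ValueError) as exc:
            errors.append(RowError(line, str(exc)))
            continue
        key = (str(row["strain"]), str(row["acaricide"]))
        unit = str(row["dose_unit"]) if pd.notna(row.get("dose_unit")) else "ug/cm2"
        if key not in datasets:
            try:
                datasets[key] = BioassayDataset(key[0], key[1], dose_unit=unit)
            except ValueError as exc:
                errors.append(RowError(line, str(exc)))
                continue
        datasets[key].append(obs)
    return list(datasets.values()), errors


def write_bioassay_csv(datasets: list[BioassayDataset], path) -> None:
    rows = []
    for ds in datasets:
        for o in ds.observations:
            rows.append(
                {
                    "strain": ds.strain,
                    "acaricide": ds.acaricide,
                    "dose": o.dose,
                    "dose_unit": ds.dose_unit,
                    "n_treated": o.n_treated,
                    "n_dead": o.n_dead,
                    "exposure_h": o.exposure_h,
                    "replicate": "" if o.replicate is None else o.replicate,
                }
            )
    pd.DataFrame(rows, columns=BIOASSAY_COLUMNS).to_csv(path, index=False)


def write_probit_report(results, tsv_path, json_path=None) -> None:
    """Toxicity-table report: one row per assay with N, slope +/- SE,
    chi2, df, LD50 and LD90 with their 95% limits, and the diagnostic
    dose. Values are rounded to 3 significant figures for display only;
    the JSON twin keeps full precision. 'ND' assays emit ``nd`` cells."""
    rows, raw = [], []
    for res in results:
        if isinstance(res, ProbitNotDetermined):
            rows.append(
                {
                    "strain": res.strain,
                    "acaricide": res.acaricide,
                    "n": ND,
                    "slope": ND,
                    "slope_se": ND,
                    "chi2": ND,
                    "df": ND,
                    "ld50": ND,
                    "ld50_ci": ND,
                    "ld90": ND,
                    "ld90_ci": ND,
                    "dd": ND,
                    "dose_unit": ND,
                }
            )
            raw.append({"strain": res.strain, "acaricide": res.acaricide, "nd": True, "reason": res.reason})
            continue
        d = res.to_dict()
        g = lambda v: format(v, ".3g")
        rows.append(
            {
                "strain": d["strain"],
                "acaricide": d["acaricide"],
                "n": d["n"],
                "slope": g(d["slope"]),
                "slope_se": g(d["slope_se"]),
                "chi2": g(d["chi2"]),
                "df": d["df"],
                "ld50": g(d["ld50"]),
                "ld50_ci": f"{g(d['ld50_ci'][0])}-{g(d['ld50_ci'][1])}",
                "ld90": g(d["ld90"]),
                "ld90_ci": f"{g(d['ld90_ci'][0])}-{g(d['ld90_ci'][1])}",
                "dd": g(d["diagnostic_dose"]),
                "dose_unit": d["dose_unit"],
            }
        )
        raw.append({**d, "nd": False})
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        Path(json_path).write_text(json.dumps(raw, indent=1))


# ---------------------------------------------------------------------------
# QS tables


def read_peak_table_csv(path, panel: list[MutationDefinition]) -> tuple[list[PeakSignal], list[RowError]]:
    """Read ``sample,mutation,height_A,height_C,height_G,height_T`` rows,
    resolving each mutation name against the panel."""
    df = pd.read_csv(path)
    need = ["sample", "mutation", "height_A", "height_C", "height_G", "height_T"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    lookup = panel_by_abbreviation(panel)
    out, errors = [], []
    for i, row in df.iterrows():
        line = i + 2
        name = str(row["mutation"])
        mut = lookup.get(name, name)
        try:
            out.append(
                PeakSignal(
                    sample=str(row["sample"]),
                    mutation=mut,
                    peak_heights={
                        b: float(row[f"height_{b}"]) for b in "ACGT" if pd.notna(row[f"height_{b}"])
                    },
                )
            )
        except (TypeError, ValueError) as exc:
            errors.append(RowError(line, str(exc)))
    return out, errors


def read_calibration_csv(path, panel: list[MutationDefinition] | None = None) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Read calibration standards grouped by mutation.

    Accepts either precomputed ratios (``mutation,resistant_fraction,
    signal_ratio``) or raw peak columns (``height_A..height_T``), in
    which case the ratio is formed from the panel's segregating
    nucleotides.
    """
    df = pd.read_csv(path)
    if "mutation" not in df.columns or "resistant_fraction" not in df.columns:
        raise ValueError(f"{path}: needs 'mutation' and 'resistant_fraction' columns")
    lookup = panel_by_abbreviation(panel) if panel else {}
    out: dict[str, tuple[list, list]] = {}
    for i, row in df.iterrows():
        name = str(row["mutation"])
        if "signal_ratio" in df.columns and pd.notna(row["signal_ratio"]):
            ratio = float(row["signal_ratio"])
        else:
            mut = lookup.get(name)
            if mut is None:
                raise ValueError(
                    f"{path} line {i + 2}: raw peak heights given but mutation "
                    f"{name!r} is not in the panel"
                )
            sig = PeakSignal(
                sample=f"std-{i}",
                mutation=mut,
                peak_heights={b: float(row[f"height_{b}"]) for b in "ACGT"},
            )
            ratio = signal_ratio(sig)
        xs, ys = out.setdefault(name, ([], []))
        xs.append(float(row["resistant_fraction"]))
        ys.append(ratio)
    return {k: (np.asarray(x), np.asarray(y)) for k, (x, y) in out.items()}


def write_curves_json(curves: dict[str, CalibrationCurve], path) -> None:
    Path(path).write_text(json.dumps({k: c.to_dict() for k, c in curves.items()}, indent=1))


def read_curves_json(path) -> dict[str, CalibrationCurve]:
    data = json.loads(Path(path).read_text())
    return {k: CalibrationCurve.from_dict(d) for k, d in data.items()}


# ---------------------------------------------------------------------------
# matrices


def write_matrix_tsv(df: pd.DataFrame, path, index_label: str = "strain") -> None:
    """Percent matrix with ``nd`` literals for NaN; byte-stable output."""
    out = df.copy()
    out = out.map(lambda v: ND if (isinstance(v, float) and not np.isfinite(v)) else format(v, ".6g"))
    out.to_csv(path, sep="\t", index_label=index_label)


def read_matrix_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.apply(pd.to_numeric, errors="coerce")


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class RunConfig:
    """Configuration of one end-to-end run.

    Any subset of inputs may be given; stages whose inputs are absent
    are recorded as skipped, never failed.
    """

    out_dir: str | Path = "acariscan_out"
    bioassay_csv: str | Path | None = None
    standards_csv: str | Path | None = None
    samples_csv: str | Path | None = None
    mortality_tsv: str | Path | None = None
    mutation_panel: str | Path | None = None  # None -> packaged default
    seed: int = 0
    ci_method: str = "delta"
    control_correction: bool = False
    dl_convention: str = "prediction-band"
    classification_threshold: float | None = None
    heatmaps: bool = True
    verbosity: str = "info"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        for name in ("bioassay_csv", "standards_csv", "samples_csv", "mortality_tsv", "mutation_panel"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")
        if self.ci_method not in ("delta", "fieller"):
            raise ValueError("ci_method must be 'delta' or 'fieller'")
        if self.dl_convention not in ("prediction-band", "width-at-bound"):
            raise ValueError("dl_convention must be 'prediction-band' or 'width-at-bound'")


@dataclass
class ReportBundle:
    """What a pipeline run produced: output paths and stage status."""

    out_dir: Path
    outputs: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)
    errors: list = field(default_factory=list)

    @property
    def log_path(self) -> Path:
        return self.out_dir / "run_log.json"


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Run every stage whose inputs are present: probit fits and the
    toxicity report, QS calibration and frequency prediction, and the
    genotype-phenotype correlation layer with heat maps. Writes a run
    log with versions, seed and every decision flag."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(out_dir=out)
    panel = load_mutation_panel(config.mutation_panel)

    # ---- probit stage -------------------------------------------------
    if config.bioassay_csv is not None:
        datasets, errs = read_bioassay_csv(config.bioassay_csv)
        bundle.errors.extend(str(e) for e in errs)
        fits: list[ProbitResults | ProbitNotDetermined] = []
        for ds in datasets:
            try:
                res = fit_probit(ds, control_correction=config.control_correction)
                res.ci_method = config.ci_method
                fits.append(res)
            except (NonIdentifiableFitError, ValueError) as exc:
                fits.append(ProbitNotDetermined(ds.strain, ds.acaricide, str(exc)))
        tsv = out / "probit_report.tsv"
        write_probit_report(fits, tsv, out / "probit_report.json")
        bundle.outputs["probit_report"] = tsv
        bundle.stages["probit"] = "run"
    else:
        bundle.stages["probit"] = "skipped"

    # ---- QS stage -----------------------------------------------------
    curves: dict[str, CalibrationCurve] = {}
    if config.standards_csv is not None:
        standards = read_calibration_csv(config.standards_csv, panel)
        lookup = panel_by_abbreviation(panel)
        for name, (xs, ys) in standards.items():
            curves[name] = QsCalibration(xs, ys, mutation=lookup.get(name, name)).fit(
                dl_convention=config.dl_convention
            )
        write_curves_json(curves, out / "calibration_curves.json")
        bundle.outputs["calibration_curves"] = out / "calibration_curves.json"
        bundle.stages["qs_calibrate"] = "run"
    else:
        bundle.stages["qs_calibrate"] = "skipped"

    freq = None
    if config.samples_csv is not None and curves:
        from .quantseq import batch_panel

        samples, errs = read_peak_table_csv(config.samples_csv, panel)
        bundle.errors.extend(str(e) for e in errs)
        freq = batch_panel(samples, curves)
        write_matrix_tsv(freq, out / "allele_frequencies.tsv")
        bundle.outputs["allele_frequencies"] = out / "allele_frequencies.tsv"
        if config.heatmaps:
            render_heatmap(
                freq, out / "allele_frequencies.png", title="QS resistance-allele frequencies (%)"
            )
            bundle.outputs["allele_frequencies_png"] = out / "allele_frequencies.png"
        bundle.stages["qs_predict"] = "run"
    else:
        bundle.stages["qs_predict"] = "skipped"

    # ---- correlation stage -------------------------------------------
    mort = None
    if config.mortality_tsv is not None:
        mort = read_matrix_tsv(config.mortality_tsv)
        if config.heatmaps:
            render_heatmap(
                mort, out / "mortality.png", title="Diagnostic-dose mortality (%)"
            )
            bundle.outputs["mortality_png"] = out / "mortality.png"
    if mort is not None and freq is not None:
        rp = ResistancePanel(mortality=mort, frequency=freq)
        cross = correlation_matrix(rp, mode="mortality_vs_frequency", seed=config.seed)
        cross.to_frame(bh_adjust=True).to_csv(out / "correlation_cross.tsv", sep="\t", index=False)
        link = correlation_matrix(rp, mode="frequency_vs_frequency", seed=config.seed)
        write_matrix_tsv(link.rho, out / "mutation_linkage_rho.tsv", index_label="mutation")
        bundle.outputs["correlation_cross"] = out / "correlation_cross.tsv"
        bundle.outputs["mutation_linkage_rho"] = out / "mutation_linkage_rho.tsv"
        bundle.stages["correlate"] = "run"
    else:
        bundle.stages["correlate"] = "skipped"

    _write_log(bundle, config)
    return bundle


def _write_log(bundle: ReportBundle, config: RunConfig) -> None:
    import acariscan

    log = {
        "acariscan_version": acariscan.__version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config": {k: str(v) if isinstance(v, Path) else v for k, v in dataclasses.asdict(config).items()},
        "stages": bundle.stages,
        "outputs": {k: str(v) for k, v in bundle.outputs.items()},
        "row_errors": bundle.errors,
    }
    bundle.log_path.write_text(json.dumps(log, indent=1))
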