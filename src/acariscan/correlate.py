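"""Phenotype-genotype correlation: Spearman rank statistics over a
strain panel, cross-correlation matrices, and heat-map reporting.

A resistance panel pairs two matrices over a shared strain axis:
diagnostic-dose mortalities (strains x acaricides, percent) and
QS allele frequencies (strains x mutations, percent). Not-determined
cells are NaN internally and serialised as 'nd'; correlations use
pairwise deletion. Small panels (the design here has 12 strains) get
permutation p-values: full enumeration up to n = 8, seeded Monte-Carlo
above that, or the usual t approximation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ResistancePanel",
    "CorrelationResult",
    "CorrelationMatrix",
    "spearman",
    "correlation_matrix",
    "render_heatmap",
]

EXACT_ENUMERATION_MAX_N = 8  # 8! = 40320 rank permutations


@dataclass
class ResistancePanel:
    """Mortality and allele-frequency matrices sharing one strain axis."""

    mortality: pd.DataFrame
    frequency: pd.DataFrame

    def __post_init__(self) -> None:
        shared = self.mortality.index.intersection(self.frequency.index)
        if len(shared) == 0:
            raise ValueError("mortality and frequency matrices share no strains")
        self.mortality = self.mortality.loc[shared].astype(float)
        self.frequency = self.frequency.loc[shared].astype(float)
        for name, df in (("mortality", self.mortality), ("frequency", self.frequency)):
            vals = df.to_numpy()
            finite = vals[np.isfinite(vals)]
            if finite.size and (finite.min() < 0 or finite.max() > 100):
                raise ValueError(f"{name} values must lie in [0, 100] or be nd")

    @property
    def strains(self) -> list[str]:
        return list(self.mortality.index)


@dataclass(frozen=True)
class CorrelationResult:
    """One Spearman correlation: rho, p, pairs used, labels."""

    rho: float
    p_value: float
    n_used: int
    label_x: str = ""
    label_y: str = ""
    method: str = "exact"

    @property
    def significant_05(self) -> bool:
        return np.isfinite(self.p_value) and self.p_value < 0.05

    @property
    def significant_01(self) -> bool:
        return np.isfinite(self.p_value) and self.p_value < 0.01

    @property
    def flag(self) -> str:
        if self.significant_01:
            return "**"
        if self.significant_05:
            return "*"
        return ""


def _rank(v: np.ndarray) -> np.ndarray:
    return stats.rankdata(v, method="average")


def _rho_of_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    sx = rx - rx.mean()
    sy = ry - ry.mean()
    den = np.sqrt((sx**2).sum() * (sy**2).sum())
    if den == 0:
        return np.nan
    return float((sx * sy).sum() / den)


def _exact_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided permutation p by full enumeration of rank pairings."""
    n = len(rx)
    perms = np.array(list(itertools.permutations(range(n))))
    ry_perm = ry[perms]  # (n!, n)
    sx = rx - rx.mean()
    sy = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    den = np.sqrt((sx**2).sum() * (sy**2).sum(axis=1))
    rhos = (sy @ sx) / den
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def _montecarlo_p(rx, ry, rho_obs, n_resamples, seed) -> float:
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_resamples):
        if abs(_rho_of_ranks(rx, rng.permutation(ry))) >= abs(rho_obs) - 1e-12:
            count += 1
    return (count + 1) / (n_resamples + 1)


def spearman(
    x,
    y,
    method: str = "auto",
    n_resamples: int = 9999,
    seed: int | None = None,
    label_x: str = "",
    label_y: str = "",
) -> CorrelationResult:
    """Spearman rank correlation with nd-aware pairwise deletion.

    Ties receive average ranks. ``method``:

    * ``"auto"`` — exact permutation enumeration for n <= 8, t
      approximation above;
    * ``"exact"`` — force enumeration (refuses n > 10);
    * ``"permutation"`` — seeded Monte-Carlo permutation test;
    * ``"asymptotic"`` — t approximation with n - 2 df.

    A constant vector (after deletion) has undefined rank correlation:
    the result carries ``rho = nan`` rather than raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        return CorrelationResult(np.nan, np.nan, n, label_x, label_y, "undefined")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(np.nan, np.nan, n, label_x, label_y, "undefined")
    rx, ry = _rank(x), _rank(y)
    rho = _rho_of_ranks(rx, ry)
    if method == "auto":
        method = "exact" if n <= EXACT_ENUMERATION_MAX_N else "asymptotic"
    if method == "exact":
        if n > 10:
            raise ValueError(f"exact enumeration refused for n = {n} (> 10); use 'permutation'")
        p = _exact_p(rx, ry, rho)
    elif method == "permutation":
        p = _montecarlo_p(rx, ry, rho, n_resamples, seed)
    elif method == "asymptotic":
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1 - rho**2))
            p = float(2 * stats.t.sf(abs(t), n - 2))
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(rho, p, n, label_x, label_y, method)


@dataclass
class CorrelationMatrix:
    """Cross-correlation of two labelled matrices (rows = columns of X,
    columns = columns of Y), with per-cell rho/p/n/flags frames."""

    rho: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    mode: str
    results: dict = field(default_factory=dict, repr=False)

    @property
    def flags(self) -> pd.DataFrame:
        def f(p):
            if not np.isfinite(p):
                return ""
            return "**" if p < 0.01 else ("*" if p < 0.05 else "")

        return self.p.map(f)

    def to_frame(self, bh_adjust: bool = False) -> pd.DataFrame:
        """Long-format table: one row per pair with rho, p, n, flag and
        optionally a Benjamini-Hochberg adjusted-p column."""
        rows = []
        for rl in self.rho.index:
            for cl in self.rho.columns:
                rows.append(
                    {
                        "x": rl,
                        "y": cl,
                        "rho": self.rho.loc[rl, cl],
                        "p_value": self.p.loc[rl, cl],
                        "n": self.n.loc[rl, cl],
                        "flag": self.flags.loc[rl, cl],
                    }
                )
        out = pd.DataFrame(rows)
        if bh_adjust:
            from statsmodels.stats.multitest import multipletests

            mask = np.isfinite(out["p_value"].to_numpy(dtype=float))
            adj = np.full(len(out), np.nan)
            if mask.any():
                adj[mask] = multipletests(out.loc[mask, "p_value"], method="fdr_bh")[1]
            out["p_bh"] = adj
        return out


def correlation_matrix(
    panel: ResistancePanel,
    mode: str = "mortality_vs_frequency",
    method: str = "auto",
    seed: int | None = None,
) -> CorrelationMatrix:
    """Full cross matrix of Spearman correlations over a strain panel.

    Modes: ``mortality_vs_frequency`` (rows = mutations, columns =
    acaricides, the genotype-phenotype table), ``frequency_vs_frequency``
    (mutation linkage, symmetric) and ``mortality_vs_mortality``.
    Pairwise nd deletion per cell; degenerate cells carry nan.
    """
    if mode == "mortality_vs_frequency":
        X, Y = panel.frequency, panel.mortality
    elif mode == "frequency_vs_frequency":
        X = Y = panel.frequency
    elif mode == "mortality_vs_mortality":
        X = Y = panel.mortality
    else:
        raise ValueError(f"unknown mode {mode!r}")
    rho = pd.DataFrame(np.nan, index=X.columns, columns=Y.columns, dtype=float)
    p = rho.copy()
    nmat = pd.DataFrame(0, index=X.columns, columns=Y.columns, dtype=int)
    results = {}
    for cx in X.columns:
        for cy in Y.columns:
            res = spearman(
                X[cx].to_numpy(), Y[cy].to_numpy(),
                method=method, seed=seed, label_x=str(cx), label_y=str(cy),
            )
            rho.loc[cx, cy] = res.rho
            p.loc[cx, cy] = res.p_value
            nmat.loc[cx, cy] = res.n_used
            results[(cx, cy)] = res
    return CorrelationMatrix(rho, p, nmat, mode, results)


def render_heatmap(
    matrix: pd.DataFrame,
    out_png,
    out_table=None,
    title: str = "",
    cmap: str = "RdYlGn",
    vmin: float = 0.0,
    vmax: float = 100.0,
    fmt: str = ".1f",
):
    """Annotated heat map of a percent matrix with nd cells rendered
    distinctly, plus a deterministic TSV of the underlying table.

    NaN cells are drawn grey and labelled 'nd'. Returns the matplotlib
    figure; the table (if ``out_table`` is given) is written with 'nd'
    literals so that repeated runs are byte-identical.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    if matrix.size == 0:
        raise ValueError("cannot render an empty matrix")
    data = matrix.astype(float)
    annot = data.map(lambda v: ("nd" if not np.isfinite(v) else format(v, fmt)))
    fig, ax = plt.subplots(
        figsize=(1.0 + 0.75 * data.shape[1], 1.0 + 0.5 * data.shape[0])
    )
    sns.heatmap(
        data,
        annot=annot,
        fmt="",
        cmap=cmap,
        vmin=vmin,
        vmax=vmax,
        linewidths=0.5,
        linecolor="white",
        cbar=True,
        ax=ax,
    )
    # grey out nd cells
    mask = ~np.isfinite(data.to_numpy())
    for (i, j) in zip(*np.where(mask)):
        ax.add_patch(plt.Rectangle((j, i), 1, 1, fill=True, color="0.85", zorder=2))
        ax.text(j + 0.5, i + 0.5, "nd", ha="center", va="center", zorder=3, fontsize=8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if out_png is not None:
        fig.savefig(out_png, dpi=150)
    if out_table is not None:
        from .io import write_matrix_tsv

        write_matrix_tsv(data, out_table)
    plt.close(fig)
    return fig
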