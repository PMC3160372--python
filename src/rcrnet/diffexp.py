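"""State-Change calling: the microarray differential-expression chain.

The chain turns probe-level intensities into signed per-gene calls
("State Changes"):

1. background correction (normal + exponential convolution model) and
   quantile normalization, with median-polish probe-set summarization for
   Affymetrix-style data (:func:`rma_summarize`) or quantile normalization
   alone for single-probe platforms;
2. a two-group linear contrast on log2 values giving a fold change and a
   (optionally empirical-Bayes moderated) t-statistic per probe
   (:func:`fit_two_group`);
3. Benjamini-Hochberg FDR correction (:func:`bh_adjust`);
4. thresholding on adjusted p, absolute linear fold change, and an optional
   abundance floor, then collapsing probes to genes
   (:func:`call_state_changes`).

A gene is a State Change if at least one of its probes passes every gate;
its direction (+1 up, -1 down) is the sign of the passing probe's fold
change.  Probes of one gene passing in opposite directions yield no call
(the gene is dropped and counted as a conflict): a signless change cannot
feed directional upstream reasoning.

The :class:`DifferentialExpression` model / :class:`DifferentialExpressionResults`
pair wraps the chain in a fit-then-inspect interface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .errors import ContractError
from .expression import CONTROL, TREATED, ExpressionMatrix

RESULT_COLUMNS = [
    "log2_fc", "t_statistic", "raw_p", "adj_p",
    "mean_intensity_control", "mean_intensity_treated", "degenerate",
]


# -- normalization ---------------------------------------------------------


def quantile_normalize(matrix):
    """Force every sample onto the common (row-mean) reference distribution.

    Accepts an :class:`ExpressionMatrix` or a plain DataFrame and returns the
    same kind.  After normalization every column holds the same multiset of
    values: the element-wise mean of the per-column order statistics.
    Idempotent; preserves row order and each column's ranking.
    """
    if isinstance(matrix, ExpressionMatrix):
        return matrix.with_values(quantile_normalize(matrix.values))
    values = matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ContractError("quantile normalization requires finite values")
    order = np.argsort(values, axis=0, kind="stable")
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        out[order[:, j], j] = reference
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def normexp_background_correct(values: np.ndarray) -> np.ndarray:
    """Per-column normal + exponential convolution background adjustment.

    Models each observed intensity as background noise N(mu, sigma^2) plus an
    exponential(theta) signal and replaces it with the posterior expected
    signal E[S | X = x], which is strictly positive and monotone in x.
    Parameters are estimated per column from the empirical density mode
    (background mean), the spread of the sub-mode intensities (sigma) and the
    mean exceedance above the mode (theta).
    """
    values = np.asarray(values, dtype=float)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        x = values[:, j]
        mu = _density_mode(x)
        below = x[x < mu]
        sigma = np.sqrt(np.mean((below - mu) ** 2)) if below.size else np.std(x)
        sigma = max(sigma, 1e-8)
        above = x[x > mu]
        theta = np.mean(above - mu) if above.size else 1.0
        theta = max(theta, 1e-8)
        a = x - mu - sigma**2 / theta
        # E[S|X=x] for the convolution model, in a numerically safe form.
        with np.errstate(divide="ignore"):
            log_ratio = stats.norm.logpdf(a / sigma) - stats.norm.logsf(-a / sigma)
        out[:, j] = a + sigma * np.exp(log_ratio)
    return np.maximum(out, 1e-8)


def _density_mode(x: np.ndarray) -> float:
    """Mode of a Gaussian kernel density estimate on a coarse grid."""
    if np.ptp(x) == 0:
        return float(x[0])
    kde = stats.gaussian_kde(x)
    grid = np.linspace(x.min(), x.max(), 256)
    return float(grid[np.argmax(kde(grid))])


def median_polish(table: np.ndarray, max_iter: int = 10, tol: float = 0.01
                  ) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Tukey median polish of a rows x columns table.

    Returns ``(overall, row_effects, col_effects, residuals)`` with the usual
    additive decomposition ``table ~= overall + row + col + residual``.
    """
    residuals = np.asarray(table, dtype=float).copy()
    overall = 0.0
    row_eff = np.zeros(residuals.shape[0])
    col_eff = np.zeros(residuals.shape[1])
    last = np.abs(residuals).sum()
    for _ in range(max_iter):
        row_med = np.median(residuals, axis=1)
        row_eff += row_med
        residuals -= row_med[:, None]
        col_med_of_row = np.median(row_eff)
        overall += col_med_of_row
        row_eff -= col_med_of_row
        col_med = np.median(residuals, axis=0)
        col_eff += col_med
        residuals -= col_med[None, :]
        row_med_of_col = np.median(col_eff)
        overall += row_med_of_col
        col_eff -= row_med_of_col
        total = np.abs(residuals).sum()
        if last == 0 or abs(last - total) < tol * last:
            break
        last = total
    return overall, row_eff, col_eff, residuals


def rma_summarize(raw: ExpressionMatrix,
                  probe_set_map: dict[str, list[str]] | None = None,
                  background: bool = True,
                  normalize: bool = True) -> ExpressionMatrix:
    """Probe-set summarization of probe-level intensities.

    Background-adjusts (normal+exponential model), quantile-normalizes,
    log2-transforms, then median-polishes each probe set's probes x samples
    block; the probe-set value per sample is ``overall + column effect``.
    ``background``/``normalize`` can be switched off for platforms (or
    tests) that need the summarization step alone.
    """
    if probe_set_map is None:
        probe_set_map = {}
        for probe, pset in raw.probe_sets.items():
            probe_set_map.setdefault(pset, []).append(probe)
        if not probe_set_map:
            probe_set_map = {p: [p] for p in raw.probe_ids}
    for pset, probes in probe_set_map.items():
        if not probes:
            raise ContractError(f"probe set {pset!r} has zero probes")
        missing = [p for p in probes if p not in raw.values.index]
        if missing:
            raise ContractError(f"probe set {pset!r} references unknown probes {missing}")

    values = raw.linear_values().to_numpy(dtype=float)
    if background:
        values = normexp_background_correct(values)
    frame = pd.DataFrame(values, index=raw.values.index, columns=raw.values.columns)
    if normalize:
        frame = quantile_normalize(frame)
    log2 = np.log2(frame)

    rows = {}
    for pset in sorted(probe_set_map):
        block = log2.loc[probe_set_map[pset]].to_numpy()
        if block.shape[0] == 1:
            rows[pset] = block[0]
        else:
            overall, _, col_eff, _ = median_polish(block)
            rows[pset] = overall + col_eff
    summary = pd.DataFrame.from_dict(rows, orient="index",
                                     columns=list(raw.values.columns))
    set_to_gene = {}
    for pset, probes in probe_set_map.items():
        genes = [raw.probe_to_gene[p] for p in probes if p in raw.probe_to_gene]
        if genes:
            set_to_gene[pset] = genes[0]
    return ExpressionMatrix(values=summary, groups=raw.groups,
                            probe_to_gene=set_to_gene, scale="log2")


# -- two-group contrast ----------------------------------------------------


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the inverse scale)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if -dif / x < 1e-8:
            break
    return float(x)


def moderate_variances(s2: np.ndarray, df: int) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes shrinkage of per-probe variances.

    Fits a scaled inverse chi-square prior (d0, s0^2) to the observed sample
    variances by moment matching on log variances (digamma/trigamma
    identities), then returns the posterior variances
    ``(d0*s0^2 + df*s2) / (d0 + df)`` together with ``(d0, s0^2)``.
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2[s2 > 0]
    if positive.size == 0:
        raise ContractError("all probes have zero variance; cannot moderate")
    z = np.log(positive)
    e = z - special.polygamma(0, df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    if positive.size > 1:
        e_var = float(np.sum((e - e_mean) ** 2) / (positive.size - 1))
        e_var -= float(special.polygamma(1, df / 2.0))
    else:
        e_var = 0.0
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_sq = float(np.exp(
            e_mean + special.polygamma(0, d0 / 2.0) - np.log(d0 / 2.0)
        ))
    else:
        # no excess spread beyond sampling noise: completely pooled prior
        d0 = np.inf
        s0_sq = float(np.mean(positive))
    if np.isinf(d0):
        post = np.full_like(s2, s0_sq)
    else:
        post = (d0 * s0_sq + df * s2) / (d0 + df)
    return post, d0, s0_sq


def fit_two_group(matrix: ExpressionMatrix,
                  moderation: str = "empirical-bayes") -> pd.DataFrame:
    """Two-group contrast per probe on log2 values.

    Returns a DataFrame indexed by probe id with columns ``log2_fc``
    (treated minus control means), ``t_statistic`` (pooled-variance t,
    optionally with empirical-Bayes variance moderation), two-sided
    ``raw_p``, BH-adjusted ``adj_p``, linear-scale group mean intensities
    and a ``degenerate`` flag for probes whose unmoderated variance is zero.
    """
    if moderation not in ("none", "empirical-bayes"):
        raise ContractError(f"unknown moderation {moderation!r}")
    log2 = matrix.log2_values()
    linear = matrix.linear_values()
    ctrl = matrix.samples_in(CONTROL)
    trt = matrix.samples_in(TREATED)
    if len(ctrl) < 2 or len(trt) < 2:
        raise ContractError("each contrasted group needs >=2 samples")
    n1, n2 = len(ctrl), len(trt)
    df_resid = n1 + n2 - 2

    a = log2[ctrl].to_numpy(dtype=float)
    b = log2[trt].to_numpy(dtype=float)
    mean_c, mean_t = a.mean(axis=1), b.mean(axis=1)
    log2_fc = mean_t - mean_c
    ss = ((a - mean_c[:, None]) ** 2).sum(axis=1) + \
         ((b - mean_t[:, None]) ** 2).sum(axis=1)
    s2 = ss / df_resid
    scale = 1.0 / n1 + 1.0 / n2

    degenerate = s2 <= 0
    if moderation == "empirical-bayes":
        post_s2, d0, _ = moderate_variances(s2, df_resid)
        df_total = df_resid + d0
        with np.errstate(divide="ignore", invalid="ignore"):
            t = log2_fc / np.sqrt(post_s2 * scale)
        degenerate = post_s2 <= 0
    else:
        df_total = float(df_resid)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(degenerate, np.nan, log2_fc / np.sqrt(s2 * scale))
    if np.isfinite(df_total):
        raw_p = 2.0 * stats.t.sf(np.abs(t), df_total)
    else:
        raw_p = 2.0 * stats.norm.sf(np.abs(t))
    raw_p = np.where(np.isnan(t), np.nan, raw_p)

    table = pd.DataFrame({
        "log2_fc": log2_fc,
        "t_statistic": t,
        "raw_p": raw_p,
        "adj_p": bh_adjust(raw_p),
        "mean_intensity_control": linear[ctrl].mean(axis=1).to_numpy(),
        "mean_intensity_treated": linear[trt].mean(axis=1).to_numpy(),
        "degenerate": degenerate,
    }, index=log2.index)
    table.index.name = "probe_id"
    return table


def bh_adjust(raw_p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1).

    NaNs are propagated unchanged (with a warning) and do not count toward
    the number of tests.
    """
    p = np.asarray(raw_p, dtype=float)
    if p.size == 0:
        return p.copy()
    finite = np.isfinite(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise ContractError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    n_nan = int((~finite).sum())
    if n_nan:
        warnings.warn(f"bh_adjust: {n_nan} NaN p-values propagated", stacklevel=2)
    if finite.any():
        out[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return out


# -- State-Change calling --------------------------------------------------


@dataclass
class DEThresholds:
    """Gates applied to each probe before it can support a State Change.

    ``fold_change_min`` is an absolute *linear* fold change (1.3 means a
    probe must move by more than x1.3 up or down, i.e. |log2 FC| >
    log2(1.3)).  ``abundance_min`` is a linear-intensity floor the probe's
    mean must clear in at least one group; set ``abundance_applies=False``
    for platforms where no floor is used.
    """

    adj_p_max: float = 0.05
    fold_change_min: float = 1.3
    abundance_min: float | None = None
    abundance_applies: bool = True

    def __post_init__(self):
        if not 0 < self.adj_p_max < 1:
            raise ContractError("adj_p_max must lie in (0, 1)")
        if self.fold_change_min <= 1:
            raise ContractError("fold_change_min must exceed 1")

    def to_dict(self) -> dict:
        return {
            "adj_p_max": self.adj_p_max,
            "fold_change_min": self.fold_change_min,
            "abundance_min": self.abundance_min,
            "abundance_applies": self.abundance_applies,
        }


@dataclass
class StateChangeSet:
    """Signed per-gene calls plus the measured-gene universe."""

    changes: dict[str, int]
    universe: set[str]
    provenance: dict = field(default_factory=dict)
    n_conflicts: int = 0
    conflict_genes: list[str] = field(default_factory=list)
    n_unmapped_probes: int = 0

    def __post_init__(self):
        if not set(self.changes) <= self.universe:
            raise ContractError("changed genes must lie inside the universe")
        if not set(self.changes.values()) <= {1, -1}:
            raise ContractError("directions must be +-1")

    def __len__(self) -> int:
        return len(self.changes)

    def flipped(self) -> "StateChangeSet":
        """Same calls with every direction negated (sign-symmetry tool)."""
        return StateChangeSet(
            changes={g: -d for g, d in self.changes.items()},
            universe=set(self.universe),
            provenance=dict(self.provenance),
            n_conflicts=self.n_conflicts,
            conflict_genes=list(self.conflict_genes),
            n_unmapped_probes=self.n_unmapped_probes,
        )

    def save(self, path: Path | str, header_lines: list[str] | None = None) -> None:
        lines = list(header_lines or [])
        lines.append("gene\tdirection\tin_universe")
        for gene in sorted(self.universe):
            lines.append(f"{gene}\t{self.changes.get(gene, 0)}\t1")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def load(cls, path: Path | str) -> "StateChangeSet":
        changes, universe = {}, set()
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            if not line.strip() or line.startswith("#") or line.startswith("gene\t"):
                continue
            gene, direction, *_ = line.split("\t")
            universe.add(gene)
            if int(direction) != 0:
                changes[gene] = int(direction)
        return cls(changes=changes, universe=universe)


def call_state_changes(results: pd.DataFrame, thresholds: DEThresholds,
                       probe_to_gene: dict[str, str]) -> StateChangeSet:
    """Collapse per-probe test results into signed per-gene State Changes."""
    log2_fc_min = np.log2(thresholds.fold_change_min)
    passing = (
        (results["adj_p"] <= thresholds.adj_p_max)
        & (results["log2_fc"].abs() > log2_fc_min)
        & ~results["adj_p"].isna()
    )
    if thresholds.abundance_applies and thresholds.abundance_min is not None:
        floor = thresholds.abundance_min
        passing &= (
            (results["mean_intensity_control"] > floor)
            | (results["mean_intensity_treated"] > floor)
        )

    universe: set[str] = set()
    directions: dict[str, set[int]] = {}
    n_unmapped = 0
    for probe in results.index:
        gene = probe_to_gene.get(str(probe))
        if gene is None:
            n_unmapped += 1
            continue
        universe.add(gene)
        if passing.loc[probe]:
            sign = 1 if results.at[probe, "log2_fc"] > 0 else -1
            directions.setdefault(gene, set()).add(sign)

    changes, conflicts = {}, []
    for gene, signs in directions.items():
        if len(signs) == 1:
            changes[gene] = next(iter(signs))
        else:
            conflicts.append(gene)
    return StateChangeSet(
        changes=changes,
        universe=universe,
        provenance={"thresholds": thresholds.to_dict()},
        n_conflicts=len(conflicts),
        conflict_genes=sorted(conflicts),
        n_unmapped_probes=n_unmapped,
    )


# -- model / results interface --------------------------------------------


class DifferentialExpression:
    """Two-group differential-expression model over an expression matrix.

    ``normalize`` selects the pre-processing applied before the contrast:
    ``"rma"`` (background + quantile + median-polish summarization, for
    probe-set platforms), ``"quantile"`` (quantile normalization only), or
    ``"none"`` (matrix used as given).
    """

    def __init__(self, matrix: ExpressionMatrix, normalize: str = "none"):
        if normalize not in ("none", "quantile", "rma"):
            raise ContractError(f"unknown normalize mode {normalize!r}")
        self.raw = matrix
        self.normalize = normalize

    def fit(self, moderation: str = "empirical-bayes"
            ) -> "DifferentialExpressionResults":
        if self.normalize == "rma":
            processed = rma_summarize(self.raw)
        elif self.normalize == "quantile":
            processed = quantile_normalize(self.raw)
        else:
            processed = self.raw
        table = fit_two_group(processed, moderation=moderation)
        return DifferentialExpressionResults(self, processed, table, moderation)


class DifferentialExpressionResults:
    """Fitted per-probe contrast results plus the State-Change caller."""

    def __init__(self, model: DifferentialExpression,
                 matrix: ExpressionMatrix, table: pd.DataFrame,
                 moderation: str):
        self.model = model
        self.matrix = matrix
        self.table = table
        self.moderation = moderation

    def state_changes(self, thresholds: DEThresholds | None = None
                      ) -> StateChangeSet:
        return call_state_changes(
            self.table, thresholds or DEThresholds(), self.matrix.probe_to_gene
        )

    def summary(self, top: int = 10) -> str:
        ordered = self.table.sort_values("adj_p")
        lines = [
            "Two-group differential expression",
            f"  probes: {len(self.table)}   "
            f"samples: {len(self.matrix.sample_ids)}   "
            f"moderation: {self.moderation}",
            f"  probes with adj_p <= 0.05: "
            f"{int((self.table['adj_p'] <= 0.05).sum())}",
            "",
            ordered.head(top).to_string(
                float_format=lambda v: f"{v:.4g}"
            ),
        ]
        return "\n".join(lines)
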