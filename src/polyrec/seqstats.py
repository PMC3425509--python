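"""Statistics on the per-read error matrix: lag-one error coupling, Poisson
overdispersion, and a binomial GLM over sequence/structure features.

All three analyses consume the same object, a binary reads-x-positions error
matrix built from accepted, indel-free alignments over the first 70 extension
positions.

* Lag-one excess: for every adjacent position pair, the observed joint error
  frequency minus the product of the two positions' individual rates (the
  position-specific product corrects for correlations imposed by the
  template itself); the mean over pairs is reported in percent per base with
  a seeded bootstrap standard error over reads.
* Dispersion: if every polymerase molecule carried the same rates, per-read
  error totals would be Poisson; a chi-square goodness-of-fit test against
  Poisson(sample mean) with bins pooled to expected counts >= 5 detects
  molecule-to-molecule heterogeneity (variance > mean).
* GLM: a binomial (logit) regression of the per-read, per-position error
  indicator on the template-base identity (three indicators, A absorbed in
  the bias), the position along the template, and the secondary-structure
  score at the seven positions from three before to three after the modelled
  base; the first and last three positions are excluded so the structure
  window is always complete.  Model quality is the squared Pearson
  correlation between predicted and observed per-position rates, and fits on
  one template can be scored on another (cross-template prediction).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .synthetic_data import BASES, TemplateSpec

__all__ = [
    "StructureProfile",
    "read_structure_tsv",
    "write_structure_tsv",
    "LagOneResult",
    "lag_one_excess",
    "DispersionResult",
    "dispersion_test",
    "GlmDesign",
    "build_design",
    "GlmFit",
    "fit_glm",
    "predict_r2",
    "GlmError",
]

MATRIX_POSITIONS = 70     # alignments are restricted to the first 70 positions
GLM_FIRST, GLM_LAST = 4, 67   # modelled positions (1-based, inclusive)


class GlmError(RuntimeError):
    """Non-convergence or separation during GLM fitting."""


# ---------------------------------------------------------------------------
# Structure profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StructureProfile:
    """Per-position pairedness score s_i = 1 - P(base i unpaired), in [0,1],
    indexed by extension position (1-based order of synthesis)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or np.any((v < 0) | (v > 1)):
            raise ValueError("structure scores must be a 1-D array in [0, 1]")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.values)


def read_structure_tsv(path: str | Path) -> StructureProfile:
    df = pd.read_csv(path, sep="\t")
    df = df.sort_values("position")
    if not np.array_equal(df["position"].to_numpy(), np.arange(1, len(df) + 1)):
        raise ValueError("structure TSV must cover positions 1..L")
    return StructureProfile(df["s"].to_numpy())


def write_structure_tsv(profile: StructureProfile, path: str | Path) -> None:
    pd.DataFrame({"position": np.arange(1, len(profile) + 1),
                  "s": profile.values}).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Lag-one excess errors
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LagOneResult:
    """Mean excess of adjacent-position joint error frequency over the
    independence expectation, in percent per base, with bootstrap SE."""

    excess_pct: float
    se_pct: float
    per_pair: np.ndarray  # excess per adjacent pair (fractions)
    n_reads: int


def lag_one_excess(matrix: np.ndarray, n_boot: int = 1000,
                   seed: int = 0) -> LagOneResult:
    """Excess lag-one errors of an error matrix.

    For each adjacent position pair (p, p+1): observed joint frequency of a
    read erring at both positions, minus the expectation n_p/N_t * n_{p+1}/N_t
    from the two per-position rates.  The mean over pairs is reported in %,
    with a seeded bootstrap (resampling reads) supplying the standard error.
    """
    X = np.asarray(matrix)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a reads x positions matrix with >= 2 reads")
    Xf = X.astype(np.float32)
    n, P = Xf.shape
    col = Xf.mean(axis=0)
    joint = (Xf[:, :-1] * Xf[:, 1:]).mean(axis=0)
    per_pair = joint - col[:-1] * col[1:]
    excess = float(per_pair.mean())

    rng = np.random.default_rng(seed)
    J = Xf[:, :-1] * Xf[:, 1:]
    boots = np.empty(n_boot)
    chunk = max(1, int(2e8 // (8 * n)))  # keep weight blocks ~modest
    done = 0
    while done < n_boot:
        b = min(chunk, n_boot - done)
        W = rng.multinomial(n, np.full(n, 1.0 / n), size=b).astype(np.float32)
        cb = (W @ Xf) / n
        jb = (W @ J) / n
        boots[done:done + b] = (jb - cb[:, :-1] * cb[:, 1:]).mean(axis=1)
        done += b
    return LagOneResult(100.0 * excess, 100.0 * float(boots.std(ddof=1)),
                        per_pair.astype(float), n)


# ---------------------------------------------------------------------------
# Poisson dispersion
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DispersionResult:
    mean: float
    variance: float
    dispersion_index: float
    chi2: float
    dof: int
    pvalue: float  # NaN flags a degenerate input (no errors / too few bins)


def dispersion_test(matrix: np.ndarray, min_reads: int = 30) -> DispersionResult:
    """Chi-square goodness of fit of per-read error totals against
    Poisson(sample mean), with bins pooled so every expected count is >= 5."""
    X = np.asarray(matrix)
    totals = X.sum(axis=1)
    n = totals.size
    if n < min_reads:
        raise ValueError(f"need >= {min_reads} reads for the chi-square test")
    mean = float(totals.mean())
    var = float(totals.var(ddof=1))
    index = var / mean if mean > 0 else float("nan")
    if mean == 0:
        return DispersionResult(mean, var, index, float("nan"), 0, float("nan"))

    kmax = int(totals.max())
    obs = np.bincount(totals.astype(np.int64), minlength=kmax + 1).astype(float)
    exp = n * sps.poisson.pmf(np.arange(kmax + 1), mean)
    exp[-1] += n * sps.poisson.sf(kmax, mean)  # fold the open tail in
    # pool adjacent bins (from the top down) until every expected count >= 5
    o_bins, e_bins = [], []
    o_acc = e_acc = 0.0
    for o, e in zip(obs[::-1], exp[::-1]):
        o_acc += o
        e_acc += e
        if e_acc >= 5:
            o_bins.append(o_acc)
            e_bins.append(e_acc)
            o_acc = e_acc = 0.0
    if o_bins and (e_acc > 0 or o_acc > 0):  # leftover low bins
        o_bins[-1] += o_acc
        e_bins[-1] += e_acc
    dof = len(o_bins) - 2  # one constraint for n, one for the estimated mean
    if dof < 1:
        return DispersionResult(mean, var, index, float("nan"), dof, float("nan"))
    o_arr, e_arr = np.array(o_bins), np.array(e_bins)
    e_arr *= o_arr.sum() / e_arr.sum()
    chi2 = float(((o_arr - e_arr) ** 2 / e_arr).sum())
    return DispersionResult(mean, var, index, chi2, dof,
                            float(sps.chi2.sf(chi2, dof)))


# ---------------------------------------------------------------------------
# GLM over sequence context and structure
# ---------------------------------------------------------------------------

_FEATURES = ["bias", "base_C", "base_G", "base_T", "position"] + [
    f"s_{d:+d}" for d in range(-3, 4)
]


@dataclass(frozen=True)
class GlmDesign:
    """Per-position design rows for the modelled positions (4..67).

    One row per modelled position; identical rows apply to every read, so a
    per-read Bernoulli design is this design with each row repeated N_t
    times.  Columns: bias, three template-base indicators (A is the
    reference, absorbed in the bias), the position scaled to (0, 1], and the
    structure score at offsets -3..+3.
    """

    frame: pd.DataFrame
    positions: np.ndarray  # 1-based modelled positions

    @property
    def exog(self) -> np.ndarray:
        return self.frame[_FEATURES].to_numpy()


def build_design(template: TemplateSpec, profile: StructureProfile,
                 first: int = GLM_FIRST, last: int = GLM_LAST) -> GlmDesign:
    """Assemble the GLM design for one template and structure profile."""
    if len(profile) < last + 3:
        raise ValueError(
            f"structure profile (len {len(profile)}) must cover positions "
            f"1..{last + 3} of the template"
        )
    tb = template.bases_by_position
    positions = np.arange(first, last + 1)
    rows = []
    s = profile.values
    for p in positions:
        base = tb[p - 1]
        row = {
            "bias": 1.0,
            "base_C": float(base == "C"),
            "base_G": float(base == "G"),
            "base_T": float(base == "T"),
            "position": p / MATRIX_POSITIONS,
        }
        for d in range(-3, 4):
            row[f"s_{d:+d}"] = s[p - 1 + d]
        rows.append(row)
    frame = pd.DataFrame(rows)
    frame.insert(0, "position_index", positions)
    return GlmDesign(frame, positions)


@dataclass
class GlmFit:
    """Fitted binomial GLM: weights with standard errors, fitted per-position
    rates, and R^2 against the observed per-position rates."""

    params: pd.Series
    bse: pd.Series
    fitted_rates: np.ndarray
    observed_rates: np.ndarray
    r2: float
    positions: np.ndarray
    n_reads: int


def _counts_from_matrix(design: GlmDesign, matrix: np.ndarray):
    X = np.asarray(matrix)
    if X.shape[1] < design.positions.max():
        raise ValueError("error matrix does not cover the modelled positions")
    cols = design.positions - 1
    successes = X[:, cols].sum(axis=0).astype(float)
    trials = np.full(len(cols), X.shape[0], dtype=float)
    return successes, trials


def _r2(pred: np.ndarray, obs: np.ndarray) -> float:
    if np.std(pred) == 0 or np.std(obs) == 0:
        return 0.0
    return float(np.corrcoef(pred, obs)[0, 1] ** 2)


def fit_glm(design: GlmDesign, matrix: np.ndarray, tol: float = 1e-8,
            maxiter: int = 200) -> GlmFit:
    """Fit the binomial GLM (logit link) by IRLS on per-read outcomes.

    Every read contributes one Bernoulli outcome per modelled position; since
    the regressors are constant within a position, the likelihood is
    aggregated to per-position binomial counts, which is mathematically
    identical (including the standard errors) and far faster.  R^2 is the
    squared Pearson correlation between the fitted and observed per-position
    rates.
    """
    successes, trials = _counts_from_matrix(design, matrix)
    endog = np.column_stack([successes, trials - successes])
    model = sm.GLM(endog, design.exog, family=sm.families.Binomial())
    try:
        res = model.fit(maxiter=maxiter, tol=tol)
    except Exception as exc:  # pragma: no cover - statsmodels raises variously
        raise GlmError(f"GLM fit failed: {exc}") from exc
    if not res.converged:
        raise GlmError(
            f"IRLS did not converge in {maxiter} iterations "
            f"(deviance {res.deviance:.3g})"
        )
    fitted = np.asarray(res.predict(design.exog))
    observed = successes / trials
    return GlmFit(
        params=pd.Series(res.params, index=_FEATURES),
        bse=pd.Series(res.bse, index=_FEATURES),
        fitted_rates=fitted,
        observed_rates=observed,
        r2=_r2(fitted, observed),
        positions=design.positions,
        n_reads=int(trials[0]),
    )


def predict_r2(fit: GlmFit, design: GlmDesign, matrix: np.ndarray) -> float:
    """Score a fitted model on another template's data: R^2 between the
    rates predicted from that template's design and its observed
    per-position rates (cross-template prediction)."""
    successes, trials = _counts_from_matrix(design, matrix)
    eta = design.exog @ fit.params.to_numpy()
    pred = 1.0 / (1.0 + np.exp(-eta))
    return _r2(pred, successes / trials)
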