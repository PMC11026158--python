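"""Exact likelihood and maximum-likelihood fitting of the two-pathway
(gamma-escape, Housworth-Stahl) crossover interference model.

Model
-----
Crossovers on a chromosome of genetic length ``L`` Morgans are the
superposition of two independent processes:

* an *interference pathway*: the 1/2-thinning (chromatid choice) of a
  stationary gamma renewal chiasma process with shape ``nu`` and rate
  ``lambda = 2 nu (1 - p)`` per Morgan, and
* an *escape pathway*: a homogeneous Poisson process with intensity
  ``p`` per Morgan.

The gap between successive interference-pathway crossovers is a
geometric mixture of gamma distributions,

    f(x) = sum_{k >= 1} 2^{-k} Gamma(x; shape = k nu, rate = lambda),

because a retained crossover is separated from the next retained one by
``k`` chiasma gaps with probability ``2^{-k}``.  Its mean is
``1 / (1 - p)`` Morgans, so the thinned pathway has intensity
``1 - p`` and the total crossover intensity is exactly 1 per Morgan for
all ``(nu, p)``.

By stationary renewal theory the density of the first crossover after
the chromosome start is ``h(x) = (1 - p) (1 - F(x))`` with ``F`` the CDF
of ``f``, and the probability of an empty chromosome from this pathway
is ``P0(L) = 1 - int_0^L h``.

Likelihood
----------
Observed crossovers cannot be attributed to a pathway, so the likelihood
of positions ``y_1 < ... < y_n`` on ``[0, L]`` sums over every subset S
assigned to the interference pathway (the complement being escape
points):

    lik = e^{-pL} * sum_S  p^{n - |S|}
          * [ P0(L)                                   if S is empty
              h(s_1) * prod f(gaps of S) * (1 - F(L - s_last))  otherwise ]

The sum is computed in O(n^2) by dynamic programming over the rightmost
interference-assigned point (never by enumerating the 2^n subsets), and
the total log-likelihood adds over meiosis-chromosome records.  For
``nu = 1`` the sum telescopes and the total log-likelihood is exactly
``-(total Morgans scored)`` regardless of the positions.

The geometric series is truncated at ``K_TERMS`` terms; the tail mass is
``2^{-K}``, chosen below 1e-16 so truncation never dominates tolerances
even when summed over cohort-scale record counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import expit, gammainc, gammaln, logit
from scipy.stats import chi2

from .genome import GenomeModel
from .simulate import MeiosisRecord, StahlParams

__all__ = [
    "StahlModel",
    "InterferenceFit",
    "LrtResult",
    "interxo_density",
    "interxo_survival",
    "stahl_loglik",
    "fit_stahl",
    "carrier_lrt",
    "records_from_meioses",
]

logger = logging.getLogger(__name__)

#: geometric-series truncation; tail mass 2^-54 ~ 5.6e-17
K_TERMS = 54

_LOG2 = np.log(2.0)
_TINY = 1e-300

#: a meiosis-chromosome observation: (genetic length in Morgans, sorted positions)
XORecord = tuple[float, np.ndarray]


class StahlModel:
    """Densities of the inter-crossover gap distribution for fixed params."""

    def __init__(self, params: StahlParams, k_terms: int = K_TERMS):
        if params.p >= 1.0:
            raise ValueError(
                "p = 1 leaves no interference pathway; the process is pure "
                "Poisson and the gap density is undefined - use the Poisson "
                "branch of stahl_loglik instead"
            )
        self.params = params
        self.k_terms = k_terms
        ks = np.arange(1, k_terms + 1, dtype=float)
        self.rate = 2.0 * params.nu * (1.0 - params.p)
        self.shapes = ks * params.nu  # (K,)
        self.log_weights = -ks * _LOG2
        self._log_rate = np.log(self.rate)
        self._gammaln_shapes = gammaln(self.shapes)

    # gap density f(x)
    def density(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if np.any(x < 0):
            raise ValueError("gap must be non-negative")
        out = np.zeros_like(x)
        pos = x > 0
        if np.any(pos):
            xp = x[pos]
            logx = np.log(xp)
            # (K, N) log-terms of the geometric gamma mixture
            lt = (
                self.log_weights[:, None]
                + self.shapes[:, None] * self._log_rate
                + (self.shapes[:, None] - 1.0) * logx[None, :]
                - self.rate * xp[None, :]
                - self._gammaln_shapes[:, None]
            )
            m = lt.max(axis=0)
            out[pos] = np.exp(m) * np.exp(lt - m[None, :]).sum(axis=0)
        return out

    # gap CDF F(x)
    def cdf(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        vals = gammainc(self.shapes[:, None], self.rate * np.clip(x, 0.0, None)[None, :])
        return np.exp(self.log_weights) @ vals

    def survival(self, x) -> np.ndarray:
        return 1.0 - self.cdf(x)

    def first_point_density(self, x) -> np.ndarray:
        """Stationary density of the first interference-pathway crossover."""
        return (1.0 - self.params.p) * self.survival(x)

    def cdf_integral(self, L) -> np.ndarray:
        """Closed-form ``int_0^L F(u) du`` using
        ``int_0^x P(a, t) dt = x P(a, x) - a P(a+1, x)``."""
        L = np.atleast_1d(np.asarray(L, dtype=float))
        z = self.rate * L
        term = L[None, :] * gammainc(self.shapes[:, None], z[None, :]) - (
            self.shapes[:, None] / self.rate
        ) * gammainc(self.shapes[:, None] + 1.0, z[None, :])
        return np.exp(self.log_weights) @ term

    def empty_prob(self, L) -> np.ndarray:
        """Probability of no interference-pathway crossover on ``[0, L]``."""
        L = np.atleast_1d(np.asarray(L, dtype=float))
        p0 = 1.0 - (1.0 - self.params.p) * (L - self.cdf_integral(L))
        return np.clip(p0, _TINY, 1.0)


def interxo_density(x, params: StahlParams) -> np.ndarray:
    """Density of the gap between successive interference-pathway crossovers."""
    return StahlModel(params).density(x)


def interxo_survival(x, params: StahlParams) -> np.ndarray:
    """``1 - F(x)`` for the inter-crossover gap distribution."""
    return StahlModel(params).survival(x)


# -- compiled data layout -----------------------------------------------------

#: guard for the largest per-record crossover count the likelihood accepts
MAX_XO_PER_RECORD = 25


class _CompiledRecords:
    """Records regrouped by per-record crossover count for vectorized
    likelihood evaluation.

    For each count ``n`` we store the lengths ``L`` (R,), positions
    (R, n), pairwise gaps (R, n(n-1)/2) and tail gaps ``L - y_j``; the
    dynamic program then runs across all records of a group at once.
    """

    def __init__(self, records: list[XORecord]):
        self.n_records = len(records)
        self.total_morgans = 0.0
        self.n_crossovers = 0
        by_n: dict[int, list[XORecord]] = {}
        for L, ys in records:
            ys = np.asarray(ys, dtype=float)
            if not L > 0:
                raise ValueError("record with non-positive genetic length")
            if len(ys) and (ys[0] < 0 or ys[-1] > L):
                raise ValueError(f"crossover position outside [0, {L}] Morgans")
            if len(ys) > 1 and np.any(np.diff(ys) < 0):
                raise ValueError("crossover positions must be sorted")
            if len(ys) > MAX_XO_PER_RECORD:
                raise ValueError(
                    f"{len(ys)} crossovers on one chromosome exceeds the guard "
                    f"({MAX_XO_PER_RECORD}); audit the input data"
                )
            self.total_morgans += float(L)
            self.n_crossovers += len(ys)
            by_n.setdefault(len(ys), []).append((float(L), ys))

        self.groups: dict[int, dict[str, np.ndarray]] = {}
        for n, recs in by_n.items():
            L_arr = np.array([r[0] for r in recs])
            if n == 0:
                uL, counts = np.unique(L_arr, return_counts=True)
                self.groups[0] = {"unique_L": uL, "counts": counts.astype(float)}
                continue
            ys = np.stack([r[1] for r in recs])  # (R, n)
            iu, ju = np.triu_indices(n, k=1)
            grp = {
                "L": L_arr,
                "ys": ys,
                "gaps": ys[:, ju] - ys[:, iu],  # (R, npairs)
                "tails": L_arr[:, None] - ys,  # (R, n)
                "pair_index": {(int(i), int(j)): k for k, (i, j) in enumerate(zip(iu, ju))},
            }
            self.groups[n] = grp


def _compiled(records) -> _CompiledRecords:
    if isinstance(records, _CompiledRecords):
        return records
    return _CompiledRecords(list(records))


def _loglik_compiled(data: _CompiledRecords, params: StahlParams) -> float:
    p = params.p
    if p >= 1.0:
        # pure Poisson with intensity 1/Morgan: density e^{-L} per record
        return -data.total_morgans
    model = StahlModel(params)
    total = 0.0
    for n, grp in data.groups.items():
        if n == 0:
            uL, counts = grp["unique_L"], grp["counts"]
            total += float(
                np.sum(counts * (-p * uL + np.log(model.empty_prob(uL))))
            )
            continue
        L = grp["L"]
        R = len(L)
        H = model.first_point_density(grp["ys"].ravel()).reshape(R, n)
        T = model.survival(grp["tails"].ravel()).reshape(R, n)
        Fg = model.density(grp["gaps"].ravel()).reshape(R, -1) if n > 1 else None
        uL, inv = np.unique(L, return_inverse=True)
        P0 = model.empty_prob(uL)[inv]
        pair = grp["pair_index"]
        # g[:, j]: sum over subsets whose rightmost interference point is j
        g = np.zeros((R, n))
        for j in range(n):
            acc = (p**j) * H[:, j]
            for i in range(j):
                acc = acc + g[:, i] * (p ** (j - i - 1)) * Fg[:, pair[(i, j)]]
            g[:, j] = acc
        lik = (p**n) * P0
        for j in range(n):
            lik = lik + g[:, j] * (p ** (n - 1 - j)) * T[:, j]
        total += float(np.sum(-p * L + np.log(np.clip(lik, _TINY, None))))
    return total


def stahl_loglik(records, params: StahlParams) -> float:
    """Total log-likelihood of meiosis-chromosome crossover records.

    ``records`` is an iterable of ``(L_morgans, sorted positions)``
    pairs (one per meiosis-chromosome); the likelihood factorizes over
    records, chromosomes sharing one ``(nu, p)``.
    """
    return _loglik_compiled(_compiled(records), params)


def records_from_meioses(
    meioses: list[MeiosisRecord], genome: GenomeModel
) -> list[XORecord]:
    """Flatten cohort meioses into per-chromosome likelihood records,
    positions converted from cM to Morgans."""
    out: list[XORecord] = []
    for m in meioses:
        for chrom in genome:
            L = chrom.genetic_length_morgans
            if chrom.name in m.crossovers:
                _, cm = m.crossovers[chrom.name]
                out.append((L, np.asarray(cm, dtype=float) / 100.0))
            else:
                out.append((L, np.empty(0)))
    return out


# -- fitting ------------------------------------------------------------------


@dataclass
class InterferenceFit:
    """Maximum-likelihood estimate of the interference parameters."""

    nu_hat: float
    p_hat: float
    loglik: float
    n_records: int
    n_crossovers: int
    converged: bool
    n_meioses: int | None = None
    se_nu: float | None = None
    se_p: float | None = None

    @property
    def params(self) -> StahlParams:
        return StahlParams(self.nu_hat, self.p_hat)


_LOGIT_FLOOR = -12.0  # p floor ~ 6e-6; boundary p = 0 is represented here


def fit_stahl(
    records,
    nu_grid: np.ndarray | None = None,
    p_grid: np.ndarray | None = None,
    xatol: float = 1e-4,
    fatol: float = 1e-7,
    maxiter: int = 400,
    compute_se: bool = False,
    n_meioses: int | None = None,
) -> InterferenceFit:
    """Joint MLE of ``(nu, p)`` by multi-start derivative-free search.

    A coarse grid over ``(ln nu, logit p)`` selects the best start, then
    Nelder-Mead refines it in the unconstrained parametrization (``p``
    is floored at ``expit(-12)``, effectively the boundary).
    """
    data = _compiled(records)
    if data.n_records == 0:
        raise ValueError("no records to fit")
    if nu_grid is None:
        nu_grid = np.array([1.5, 3.0, 6.0, 10.0, 16.0])
    if p_grid is None:
        p_grid = np.array([0.005, 0.02, 0.05, 0.12, 0.3])

    def negll(z: np.ndarray) -> float:
        nu = float(np.exp(z[0]))
        pz = max(float(z[1]), _LOGIT_FLOOR)
        p = float(expit(pz))
        try:
            return -_loglik_compiled(data, StahlParams(nu, p))
        except (ValueError, FloatingPointError):
            return np.inf

    starts = [
        np.array([np.log(nu), logit(p)]) for nu in nu_grid for p in p_grid
    ]
    grid_vals = [negll(z) for z in starts]
    z0 = starts[int(np.argmin(grid_vals))]
    res = optimize.minimize(
        negll,
        z0,
        method="Nelder-Mead",
        options={"xatol": xatol, "fatol": fatol, "maxiter": maxiter, "maxfev": 2 * maxiter},
    )
    converged = bool(res.success)
    if not converged:
        logger.warning("fit_stahl: optimizer did not converge (%s)", res.message)
    nu_hat = float(np.exp(res.x[0]))
    p_hat = float(expit(max(float(res.x[1]), _LOGIT_FLOOR)))
    fit = InterferenceFit(
        nu_hat=nu_hat,
        p_hat=p_hat,
        loglik=float(-res.fun),
        n_records=data.n_records,
        n_crossovers=data.n_crossovers,
        converged=converged,
        n_meioses=n_meioses,
    )
    if compute_se:
        fit.se_nu, fit.se_p = _observed_information_se(data, nu_hat, p_hat)
    return fit


def _observed_information_se(
    data: _CompiledRecords, nu: float, p: float
) -> tuple[float | None, float | None]:
    """Standard errors from the observed information (central differences
    on the (nu, p) scale); ``None`` when the Hessian is not positive
    definite or ``p`` sits on the boundary."""
    if p < 1e-4:
        return None, None
    h_nu, h_p = 1e-3 * max(nu, 1.0), min(1e-4, p / 4)

    def ll(a, b):
        return _loglik_compiled(data, StahlParams(a, min(max(b, 0.0), 1.0 - 1e-9)))

    f0 = ll(nu, p)
    d2a = (ll(nu + h_nu, p) - 2 * f0 + ll(nu - h_nu, p)) / h_nu**2
    d2b = (ll(nu, p + h_p) - 2 * f0 + ll(nu, p - h_p)) / h_p**2
    dab = (
        ll(nu + h_nu, p + h_p) - ll(nu + h_nu, p - h_p) - ll(nu - h_nu, p + h_p) + ll(nu - h_nu, p - h_p)
    ) / (4 * h_nu * h_p)
    info = -np.array([[d2a, dab], [dab, d2b]])
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return None, None
    if cov[0, 0] <= 0 or cov[1, 1] <= 0:
        return None, None
    return float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))


@dataclass
class LrtResult:
    """Likelihood-ratio test of shared vs group-specific ``(nu, p)``."""

    chi2: float
    df: int
    p_value: float
    fit_carrier: InterferenceFit
    fit_noncarrier: InterferenceFit
    fit_pooled: InterferenceFit

    @property
    def converged(self) -> bool:
        return (
            self.fit_carrier.converged
            and self.fit_noncarrier.converged
            and self.fit_pooled.converged
        )


def carrier_lrt(carrier_records, noncarrier_records, **fit_kwargs) -> LrtResult:
    """Test whether carrier and noncarrier crossovers share one
    interference-parameter pair.

    Fits the model separately in the two groups and pooled;
    ``chi2 = 2 (ll_carrier + ll_noncarrier - ll_pooled)`` is referred to
    a chi-squared distribution with 2 degrees of freedom (Wilks).
    """
    carrier = _compiled(carrier_records)
    noncarrier = _compiled(noncarrier_records)
    if carrier.n_records == 0 or noncarrier.n_records == 0:
        raise ValueError("both groups must be non-empty")
    fc = fit_stahl(carrier, **fit_kwargs)
    fn = fit_stahl(noncarrier, **fit_kwargs)
    merged: list[XORecord] = []
    for comp in (carrier, noncarrier):
        for n, grp in comp.groups.items():
            if n == 0:
                for L, c in zip(grp["unique_L"], grp["counts"]):
                    merged.extend([(float(L), np.empty(0))] * int(c))
            else:
                for L, ys in zip(grp["L"], grp["ys"]):
                    merged.append((float(L), ys))
    fp = fit_stahl(merged, **fit_kwargs)
    stat = 2.0 * (fc.loglik + fn.loglik - fp.loglik)
    if stat < -1e-6:
        logger.warning("carrier_lrt: negative LRT statistic %.3g clamped to 0", stat)
    stat = max(stat, 0.0)
    return LrtResult(
        chi2=stat,
        df=2,
        p_value=float(chi2.sf(stat, df=2)),
        fit_carrier=fc,
        fit_noncarrier=fn,
        fit_pooled=fp,
    )
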