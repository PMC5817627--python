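"""Differential-methylation tests on clustered regions.

Region counts are modelled hierarchically: within a replicate the
methylated count is binomial, and the replicate-level methylation
proportion varies around the group mean with a beta-binomial dispersion
phi (the intra-class correlation of calls within a replicate), so

    Var(X_i / N_i) = mu (1 - mu) [1 + (N_i - 1) phi] / N_i.

Group means are coverage-weighted fractions, mu = sum X_i / sum N_i.
Per-region dispersion estimates from a handful of replicates are far too
noisy to use directly, so they are shrunk toward a prior fitted across
all regions of a group (empirical Bayes on the log scale).  Group means
are then compared with a Wald test, p-values adjusted per comparison by
Benjamini-Hochberg, and regions passing the effect-size and significance
thresholds are flagged as DMRs.  Any number of groups is supported; every
unordered pair is tested.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import polygamma
from scipy.stats import norm

_PHI_EPS = 1e-8  # clamp ceiling: phi <= 1 - eps
_PHI_FLOOR = 1e-4  # floor before taking logs (raw estimates can be 0)
_TAU2_FLOOR = 1e-3  # minimum prior variance on the log scale
_FALLBACK_LOG_PHI = math.log(0.01)
_FALLBACK_TAU = 1.0


@dataclass(frozen=True)
class TestParams:
    """Thresholds of the DMR-calling stage.

    A region is a DMR for a comparison when |diff| >= min_diff, p <= max_p
    and q <= max_q.  Set max_q to 1 to disable the FDR gate.
    """

    min_diff: float = 0.10
    max_p: float = 0.05
    max_q: float = 0.05

    def __post_init__(self) -> None:
        for name in ("min_diff", "max_p", "max_q"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class GroupEstimate:
    """Per-region, per-group estimate.

    mu is the coverage-weighted methylation fraction; phi_raw the
    method-of-moments dispersion (NaN when fewer than two replicates with
    coverage); phi the working (possibly shrunken) dispersion used for
    the variance of mu.
    """

    mu: float
    phi_raw: float  # NaN when undefined
    phi: float
    ns: np.ndarray  # per-replicate coverage, zero-coverage reps removed
    k: int  # replicates with coverage
    phi_mom: float = float("nan")  # moment estimate before clamping at zero

    @property
    def testable(self) -> bool:
        return self.k > 0

    def var_mu(self) -> float:
        """Model variance of mu with coverage weights w_i = N_i / sum N."""
        n_tot = float(self.ns.sum())
        w = self.ns / n_tot
        # at the boundaries clamp mu so the variance cannot degenerate to 0
        mu = min(max(self.mu, 1.0 / (2.0 * n_tot)), 1.0 - 1.0 / (2.0 * n_tot))
        scale = np.sum(w**2 * (1.0 + (self.ns - 1.0) * self.phi) / self.ns)
        return float(mu * (1.0 - mu) * scale)


def estimate_group(xs: Sequence[float], ns: Sequence[float]) -> GroupEstimate:
    """Weighted group mean and raw method-of-moments dispersion.

    Solves the coverage-weighted residual variance around mu for phi:
    with w_i = N_i / sum N and p_i = X_i / N_i,

        E[ sum w_i (p_i - mu)^2 ] = sum w_i (1 - w_i) Var(p_i),

    with Var(p_i) the beta-binomial variance above.  phi is clamped to
    [0, 1 - eps]; a single replicate leaves phi_raw undefined (NaN),
    flagging the region for full shrinkage to the prior.
    """
    xs = np.asarray(xs, dtype=float)
    ns = np.asarray(ns, dtype=float)
    keep = ns > 0
    xs, ns = xs[keep], ns[keep]
    k = int(keep.sum())
    if k == 0:
        return GroupEstimate(math.nan, math.nan, 0.0, ns, 0)
    n_tot = ns.sum()
    mu = float(xs.sum() / n_tot)
    if k < 2 or mu in (0.0, 1.0):
        # no residual information: dispersion comes entirely from the prior
        return GroupEstimate(mu, math.nan, 0.0, ns, k)
    w = ns / n_tot
    p = xs / ns
    s_obs = float(np.sum(w * (p - mu) ** 2))
    v0 = mu * (1.0 - mu)
    a = float(np.sum(w * (1.0 - w) * v0 / ns))
    b = float(np.sum(w * (1.0 - w) * v0 * (ns - 1.0) / ns))
    if b <= 0.0:  # all N_i == 1: binomial only, no dispersion information
        return GroupEstimate(mu, math.nan, 0.0, ns, k)
    phi_mom = (s_obs - a) / b
    phi_raw = min(max(phi_mom, 0.0), 1.0 - _PHI_EPS)
    return GroupEstimate(mu, phi_raw, phi_raw, ns, k, phi_mom=phi_mom)


def shrink_dispersion(
    estimates: Sequence[GroupEstimate],
    prior: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Shrink each estimate's phi toward an empirical prior, in place.

    The prior is a normal on log phi.  Its location is the log of the
    mean raw dispersion across regions (the raw estimates are roughly
    unbiased on the natural scale, so averaging there avoids the downward
    Jensen bias of averaging logs); its variance is the excess of the
    observed log-dispersion spread over the sampling noise of a
    (k-1)-degree-of-freedom variance estimate, trigamma((k-1)/2).  Each
    region's log phi* is the precision-weighted blend of its own estimate
    and the prior; regions with undefined raw phi take the prior mean.
    With fewer than two defined estimates a fixed fallback prior
    (location log 0.01, scale 1) is used.  Returns (m_hat, tau_hat).
    """
    defined = [e for e in estimates if not math.isnan(e.phi_raw)]
    if prior is not None:
        m_hat, tau_hat = prior
    elif len(defined) < 2:
        m_hat, tau_hat = _FALLBACK_LOG_PHI, _FALLBACK_TAU
    else:
        raws = np.array([e.phi_raw for e in defined])
        # the location averages the unclamped moment estimates: clamping at
        # zero would bias the prior upward when the true dispersion is ~0
        moments = np.array([e.phi_mom for e in defined])
        m_hat = math.log(max(float(moments.mean()), _PHI_FLOOR))
        # prior scale from the strictly positive estimates: estimates clamped
        # at zero carry no usable log-scale spread and would inflate tau
        noise = np.array([float(polygamma(1, (e.k - 1) / 2.0)) for e in defined])
        pos = raws > 0
        if int(pos.sum()) >= 2:
            tau2 = max(
                float(np.log(raws[pos]).var()) - float(noise[pos].mean()),
                _TAU2_FLOOR,
            )
            tau_hat = math.sqrt(tau2)
        else:
            tau_hat = _FALLBACK_TAU
    tau2 = tau_hat * tau_hat
    for e in estimates:
        if math.isnan(e.phi_raw):
            e.phi = math.exp(m_hat)
            continue
        v = float(polygamma(1, (e.k - 1) / 2.0)) if e.k >= 2 else math.inf
        log_raw = math.log(max(e.phi_raw, _PHI_FLOOR))
        log_star = (log_raw / v + m_hat / tau2) / (1.0 / v + 1.0 / tau2)
        e.phi = min(math.exp(log_star), 1.0 - _PHI_EPS)
    return m_hat, tau_hat


def wald_test(est_a: GroupEstimate, est_b: GroupEstimate) -> tuple[float, float]:
    """Wald statistic and two-sided normal p-value for mu_a - mu_b."""
    if not (est_a.testable and est_b.testable):
        return math.nan, math.nan
    var = est_a.var_mu() + est_b.var_mu()
    diff = est_a.mu - est_b.mu
    if var <= 0.0:
        return 0.0, 1.0  # degenerate after clamping
    z = diff / math.sqrt(var)
    p = 2.0 * float(norm.sf(abs(z)))
    return z, p


def adjust_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaNs pass through.

    q_(k) = min_{j >= k} m * p_(j) / j, capped at 1, over the m non-NaN
    p-values.
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    m = int(ok.sum())
    if m == 0:
        return q
    pv = p[ok]
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    qv = np.empty(m)
    qv[order] = np.minimum(ranked, 1.0)
    q[ok] = qv
    return q


def _pair_columns(a: str, b: str) -> dict[str, str]:
    tag = f"{a}->{b}"
    return {f: f"{tag}:{f}" for f in ("diff", "wald", "p", "q", "dmr")}


def call_dmrs(
    regions: pd.DataFrame,
    groups: Mapping[str, Sequence[str]],
    params: TestParams | None = None,
) -> pd.DataFrame:
    """Test every unordered group pair on every region.

    ``regions`` is a region table (chrom, start, end, CpG, then
    ``<sample>:N`` / ``<sample>:X`` columns); ``groups`` maps group name
    to its sample names.  Returns one row per region with per-group mu
    columns and, per comparison, diff (mu_A - mu_B), the Wald statistic,
    p, BH q (adjusted within the comparison), and the DMR flag.
    Untestable comparisons (a group with zero coverage) carry NaN
    statistics rather than being dropped.
    """
    if params is None:
        params = TestParams()
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g, samples in groups.items():
        if len(samples) == 0:
            raise ValueError(f"group {g!r} has no samples")
    out = regions[["chrom", "start", "end", "CpG"]].copy()
    n_regions = len(regions)

    # per-group estimates for every region, then one shared shrinkage per group
    estimates: dict[str, list[GroupEstimate]] = {}
    for g, samples in groups.items():
        ests = []
        for _, row in regions.iterrows():
            xs = [row[f"{s}:X"] for s in samples]
            ns = [row[f"{s}:N"] for s in samples]
            ests.append(estimate_group(xs, ns))
        shrink_dispersion(ests)
        estimates[g] = ests
        out[f"{g}:mu"] = [e.mu for e in ests]

    for ga, gb in itertools.combinations(groups, 2):
        cols = _pair_columns(ga, gb)
        diffs = np.full(n_regions, np.nan)
        walds = np.full(n_regions, np.nan)
        ps = np.full(n_regions, np.nan)
        for i, (ea, eb) in enumerate(zip(estimates[ga], estimates[gb])):
            if not (ea.testable and eb.testable):
                continue
            diffs[i] = ea.mu - eb.mu
            walds[i], ps[i] = wald_test(ea, eb)
        qs = adjust_fdr(ps)
        flags = (
            (np.abs(diffs) >= params.min_diff)
            & (ps <= params.max_p)
            & (qs <= params.max_q)
        )
        out[cols["diff"]] = diffs
        out[cols["wald"]] = walds
        out[cols["p"]] = ps
        out[cols["q"]] = qs
        out[cols["dmr"]] = np.where(np.isnan(ps), None, flags)
    return out
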