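"""Two-group expression simulator with planted rank-reversal structure.

The generator emulates the situation the signature method targets: an
anchor gene (ERG) whose expression is elevated in fusion-positive (TFP)
samples, so that its within-sample order relative to a handful of stably
expressed *planted partner* genes reverses in TFP but not in
fusion-negative (TFN) samples.  Everything is log-normal:

* The anchor sits at log-mean ``mu_mid - erg_shift/2`` in TFN samples and
  gains ``erg_shift`` in TFP samples, with tight within-group dispersion
  (``noise_sd/5``).
* Planted partners sit near ``mu_mid`` (small alternating offsets, as
  fractions of ``erg_shift``) with moderate dispersion
  (``0.8*noise_sd``).  At the default three-noise-SD shift each pair is
  therefore individually imperfect — a few percent of samples vote wrong
  on either side of the margin, driven mostly by partner-specific noise —
  which is what gives a majority-vote ensemble something to gain, as in
  real cohorts where no single gene pair is a perfect fusion reporter.
  The error rates shrink rapidly as ``erg_shift`` grows.
* Background genes are split into a stable tier (``noise_sd/5``) and an
  unstable tier (``3*noise_sd``); their baselines are drawn above the
  anchor's dynamic range (rejection sampling outside the window
  ``[anchor TFN mean - 1.5*noise_sd, anchor TFP mean + 1.5*noise_sd]``) so
  that no background pair accidentally reproduces the planted reversal.
  Partner dispersion lies between the two background tiers, so the fused
  stability ranking places partners directly after the stable tier; the
  default stable fraction keeps the stable tier smaller than the bottom
  quartile, which is what lets the planted partners qualify as reference
  genes.

An optional per-sample strictly increasing distortion emulates platform or
normalisation differences; it changes every value but no within-sample
rank, which is precisely the invariance the pair statistics rely on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import TFN, TFP

#: Partner baseline offsets (fractions of ``erg_shift``) straddling the
#: anchor midpoint.  Positive offsets shave the sensitivity-side margin,
#: negative ones the specificity side; with partner dispersion
#: 0.8*noise_sd these set per-pair error rates of roughly 3-15% at the
#: default three-noise-SD shift, so single pairs are reliably imperfect
#: and a majority vote has something to gain.
PARTNER_OFFSETS = (0.15, -0.15, 0.22, -0.22, 0.0)

_PARTNER_SD_FACTOR = 0.8  # partner dispersion, in units of noise_sd

_BG_MU_ABOVE = 2.5  # background baseline centre, log-units above mu_mid
_BG_MU_SD = 0.8


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated two-group cohort."""

    n_genes: int = 1000
    n_tfn: int = 100
    n_tfp: int = 50
    n_planted_partners: int = 5
    erg_shift: float = 1.5  # log-scale anchor gain in TFP (3 x noise_sd)
    noise_sd: float = 0.5
    frac_stable: float = 0.15
    monotone_distort: bool = False
    seed: int = 0
    anchor: str = "ERG"
    mu_mid: float = 5.0

    def __post_init__(self):
        if self.n_genes <= self.n_planted_partners + 1:
            raise ValueError("n_genes must exceed n_planted_partners + 1")
        if self.n_tfn < 1 or self.n_tfp < 1:
            raise ValueError("need at least one sample per group")
        if self.n_planted_partners < 1:
            raise ValueError("need at least one planted partner")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.erg_shift < 0:
            raise ValueError("erg_shift must be nonnegative")
        if not 0.0 <= self.frac_stable <= 1.0:
            raise ValueError("frac_stable must be in [0, 1]")


@dataclass(frozen=True)
class SimTruth:
    labels: pd.Series
    planted_partners: frozenset[str]


def simulate(cfg: SimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Generate an expression matrix and its ground truth.

    Bitwise reproducible for a fixed config (one PCG stream seeded by
    ``cfg.seed``).  Sample ids are ``S0001..``, TFN first; background
    genes ``G0001..``; partners ``P01..``.
    """
    rng = np.random.default_rng(cfg.seed)
    n_samples = cfg.n_tfn + cfg.n_tfp
    n_bg = cfg.n_genes - 1 - cfg.n_planted_partners
    k = cfg.n_planted_partners

    mu_tfn_anchor = cfg.mu_mid - cfg.erg_shift / 2.0
    mu_tfp_anchor = cfg.mu_mid + cfg.erg_shift / 2.0
    tight_sd = cfg.noise_sd / 5.0

    offsets = np.array([PARTNER_OFFSETS[i % len(PARTNER_OFFSETS)] for i in range(k)])
    partner_mu = cfg.mu_mid + offsets * cfg.erg_shift + rng.uniform(-0.02, 0.02, k)
    partner_sd = _PARTNER_SD_FACTOR * cfg.noise_sd

    lo = mu_tfn_anchor - 1.5 * cfg.noise_sd
    hi = mu_tfp_anchor + 1.5 * cfg.noise_sd
    bg_mu = np.empty(n_bg)
    filled = 0
    for _ in range(1000):
        need = n_bg - filled
        if need == 0:
            break
        draw = rng.normal(cfg.mu_mid + _BG_MU_ABOVE, _BG_MU_SD, need)
        ok = draw[(draw < lo) | (draw > hi)]
        bg_mu[filled:filled + len(ok)] = ok
        filled += len(ok)
    else:  # pragma: no cover - would need a pathological window
        raise ValueError("could not place background genes outside the anchor window")

    n_stable = int(round(cfg.frac_stable * n_bg))
    bg_sd = np.full(n_bg, 3.0 * cfg.noise_sd)
    stable_idx = rng.permutation(n_bg)[:n_stable]
    bg_sd[stable_idx] = tight_sd

    gene_ids = (
        [cfg.anchor]
        + [f"P{i + 1:02d}" for i in range(k)]
        + [f"G{i + 1:04d}" for i in range(n_bg)]
    )
    sample_ids = [f"S{i + 1:04d}" for i in range(n_samples)]
    labels = pd.Series(
        [TFN] * cfg.n_tfn + [TFP] * cfg.n_tfp, index=sample_ids, name="label"
    )

    mu = np.concatenate([[0.0], partner_mu, bg_mu])  # anchor row patched below
    sd = np.concatenate([[tight_sd], np.full(k, partner_sd), bg_sd])
    log_x = mu[:, None] + sd[:, None] * rng.standard_normal((cfg.n_genes, n_samples))
    anchor_mu = np.full(n_samples, mu_tfn_anchor)
    anchor_mu[cfg.n_tfn:] = mu_tfp_anchor
    log_x[0] = anchor_mu + tight_sd * rng.standard_normal(n_samples)

    m = pd.DataFrame(np.exp(log_x), index=gene_ids, columns=sample_ids)
    if cfg.monotone_distort:
        m = distort_monotone(m, seed=int(rng.integers(2**31)))
    truth = SimTruth(
        labels=labels,
        planted_partners=frozenset(gene_ids[1:1 + k]),
    )
    return m, truth


def distort_monotone(m: pd.DataFrame, seed: int, n_knots: int = 8) -> pd.DataFrame:
    """Apply an independent strictly increasing map to every sample column.

    Each column passes through a random increasing piecewise-linear spline
    (positive slopes everywhere), so all values change but every
    within-sample rank — and hence every REO — is exactly preserved.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    out = m.copy()
    for col in m.columns:
        x = m[col].to_numpy(dtype=float)
        lo, hi = x.min(), x.max()
        if lo == hi:
            out[col] = x * rng.uniform(0.5, 2.0) + rng.uniform(0.0, 1.0)
            continue
        knots_x = np.linspace(lo, hi, n_knots)
        knots_y = np.cumsum(rng.uniform(0.2, 2.0, n_knots))
        scale = rng.uniform(0.5, 20.0)
        shift = rng.uniform(0.0, 100.0)
        out[col] = np.interp(x, knots_x, knots_y) * scale + shift
    return out
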