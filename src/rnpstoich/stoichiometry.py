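"""Closed-form dual-colour labelling models and copy-number inversion.

Two labelling schemes are modelled:

* **Binomial SNAP labelling** — each of the ``k`` polypeptides in a complex
  independently carries a dye with probability ``p_label``; a labelled
  polypeptide carries dye A with probability ``q_dyeA``, otherwise dye B.
  A complex is scored *dual* if it carries at least one dye of each species.

* **Poisson body labelling** — each RNA molecule is drawn from a colour-A or
  colour-B preparation and carries a Poisson-distributed number of dyes of
  that single colour; it is detected iff it carries at least one dye.

Both forward models are inverted in closed form to estimate the fraction of
complexes holding two copies (of the protein, or of the RNA) from an observed
dual-colour fraction among detected complexes.  Confidence intervals are
propagated through the monotone inversion, either from a Wilson score interval
on the dual fraction or a multinomial bootstrap over complexes.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from ._types import CopyNumberEstimate, DualColourCounts

__all__ = [
    "dual_label_distribution",
    "expected_dual_fraction",
    "both_labeled_fraction",
    "poisson_detection_probability",
    "rna_dual_fraction",
    "infer_two_copy_fraction",
    "infer_rna_mixture",
    "snap_dual_fraction_mixture",
    "SnapCopyNumberEstimator",
    "RnaCopyNumberEstimator",
]


def _check_prob(value: float, name: str) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {value}")


# ---------------------------------------------------------------------------
# binomial SNAP-labelling forward model
# ---------------------------------------------------------------------------

def dual_label_distribution(k: int, p_label: float, q_dyeA: float) -> dict[str, float]:
    """Category probabilities for a k-copy complex under binomial labelling.

    Each polypeptide independently ends up unlabelled (prob ``1 - p_label``),
    dye-A labelled (``p_label * q_dyeA``) or dye-B labelled
    (``p_label * (1 - q_dyeA)``).  Inclusion-exclusion over the k independent
    polypeptides gives exact category probabilities:

    ``dual``       = P(>=1 A and >=1 B) = 1 - (1-pA)^k - (1-pB)^k + (1-p)^k
    ``A_only``     = (1-pB)^k - (1-p)^k
    ``B_only``     = (1-pA)^k - (1-p)^k
    ``undetected`` = (1-p)^k

    Returns a dict with those four keys; probabilities sum to 1.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    _check_prob(p_label, "p_label")
    _check_prob(q_dyeA, "q_dyeA")
    p_a = p_label * q_dyeA
    p_b = p_label * (1.0 - q_dyeA)
    none_a = (1.0 - p_a) ** k      # no dye A on any copy
    none_b = (1.0 - p_b) ** k
    none_any = (1.0 - p_label) ** k
    return {
        "dual": 1.0 - none_a - none_b + none_any,
        "A_only": none_b - none_any,
        "B_only": none_a - none_any,
        "undetected": none_any,
    }


def expected_dual_fraction(
    k: int, p_label: float, q_dyeA: float, conditional_on_detection: bool = False
) -> float:
    """Dual-colour probability for a k-copy complex.

    With ``conditional_on_detection`` the probability is renormalised to
    complexes carrying at least one dye (what the assay can see).  Returns
    ``nan`` when nothing is detectable (p_label = 0 with the conditional flag).
    """
    dist = dual_label_distribution(k, p_label, q_dyeA)
    if not conditional_on_detection:
        return dist["dual"]
    detected = 1.0 - dist["undetected"]
    if detected <= 0.0:
        return float("nan")
    return dist["dual"] / detected


def both_labeled_fraction(k: int, p_label: float) -> float:
    """Probability that all k polypeptides of a complex carry a dye: p_label**k."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    _check_prob(p_label, "p_label")
    return p_label ** k


def snap_dual_fraction_mixture(
    two_copy_fraction: float, p_label: float, q_dyeA: float = 0.5
) -> float:
    """Forward model: dual fraction among *detected* complexes for a 1/2-copy mixture.

    A 1-copy complex can never be dual; the mixture dual fraction is
    ``phi * dual_2 / (phi * det_2 + (1 - phi) * det_1)`` with phi the 2-copy
    weight and det_k = 1 - (1 - p_label)**k the detection probability.
    """
    _check_prob(two_copy_fraction, "two_copy_fraction")
    _check_prob(p_label, "p_label")
    if p_label == 0.0:
        return float("nan")
    d2 = dual_label_distribution(2, p_label, q_dyeA)
    det1 = p_label
    det2 = 1.0 - d2["undetected"]
    phi = two_copy_fraction
    denom = phi * det2 + (1.0 - phi) * det1
    return phi * d2["dual"] / denom


# ---------------------------------------------------------------------------
# Poisson body-labelling forward model (RNA)
# ---------------------------------------------------------------------------

def poisson_detection_probability(poisson_mean: float) -> float:
    """Probability that a body-labelled RNA carries >=1 dye: 1 - exp(-mean)."""
    if poisson_mean < 0:
        raise ValueError(f"poisson_mean must be >= 0, got {poisson_mean}")
    return -math.expm1(-poisson_mean)


def rna_dual_fraction(
    two_rna_fraction: float, poisson_mean: float, colourA_fraction: float = 0.5
) -> float:
    """Forward model: dual-colour fraction among detected RNPs.

    With L = 1 - exp(-poisson_mean) the per-RNA detection probability and
    a = colourA_fraction, a 2-RNA particle is dual iff its RNAs come from
    different preparations and both are detected (prob ``2 a (1-a) L^2``);
    it is detected iff at least one RNA is (prob ``1 - (1-L)^2``); a 1-RNA
    particle is detected with probability L and is never dual:

        dual | detected = f2 * 2a(1-a) L^2 / [(1-f2) L + f2 (1 - (1-L)^2)]
    """
    _check_prob(two_rna_fraction, "two_rna_fraction")
    _check_prob(colourA_fraction, "colourA_fraction")
    L = poisson_detection_probability(poisson_mean)
    if L <= 0.0:
        return float("nan")  # nothing detected
    a = colourA_fraction
    f2 = two_rna_fraction
    num = f2 * 2.0 * a * (1.0 - a) * L * L
    den = (1.0 - f2) * L + f2 * (1.0 - (1.0 - L) ** 2)
    return num / den


# ---------------------------------------------------------------------------
# inversion: observed dual fraction -> copy-number mixture
# ---------------------------------------------------------------------------

def _invert_snap(d: float, p_label: float, q_dyeA: float) -> tuple[float, bool]:
    """Solve the binomial mixture model for the 2-copy weight phi.

    d = phi*dual2 / (phi*det2 + (1-phi)*det1)  =>
    phi = d*det1 / (dual2 - d*(det2 - det1)), clipped to [0, 1].
    Returns (phi, out_of_model) where out_of_model flags d above the phi=1
    maximum (or an otherwise unsolvable observation).
    """
    dist2 = dual_label_distribution(2, p_label, q_dyeA)
    dual2 = dist2["dual"]
    det1 = p_label
    det2 = 1.0 - dist2["undetected"]
    if dual2 <= 0.0:
        # model cannot produce dual events at all
        return (0.0, d > 0.0)
    d_max = dual2 / det2  # dual fraction at phi = 1
    if d >= d_max:
        return (1.0, d > d_max + 1e-12)
    phi = d * det1 / (dual2 - d * (det2 - det1))
    return (float(np.clip(phi, 0.0, 1.0)), False)


def _invert_rna(d: float, poisson_mean: float, colourA_fraction: float) -> tuple[float, bool]:
    """Closed-form inversion of :func:`rna_dual_fraction`.

    f2 = d*B / (A - d*(C - B)) with A = 2a(1-a)L^2, B = L, C = 1-(1-L)^2.
    """
    L = poisson_detection_probability(poisson_mean)
    if L <= 0.0:
        raise ValueError("poisson_mean = 0: no RNA is detectable, mixture undefined")
    a = colourA_fraction
    A = 2.0 * a * (1.0 - a) * L * L
    B = L
    C = 1.0 - (1.0 - L) ** 2
    if A <= 0.0:
        return (0.0, d > 0.0)
    d_max = A / C
    if d >= d_max:
        return (1.0, d > d_max + 1e-12)
    f2 = d * B / (A - d * (C - B))
    return (float(np.clip(f2, 0.0, 1.0)), False)


def _wilson_interval(n_success: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    p = n_success / n
    denom = 1.0 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return (max(0.0, centre - half), min(1.0, centre + half))


class _CopyNumberEstimatorBase(BaseEstimator):
    """Shared fitting machinery for the two copy-number estimators."""

    #: subclasses set these
    _model_name = ""

    def __init__(self, ci_method: str = "bootstrap", n_boot: int = 1000,
                 confidence: float = 0.95, random_state: Optional[int] = 0):
        self.ci_method = ci_method
        self.n_boot = n_boot
        self.confidence = confidence
        self.random_state = random_state

    def _invert(self, d: float) -> tuple[float, bool]:  # pragma: no cover - abstract
        raise NotImplementedError

    def fit(self, X: DualColourCounts, y=None) -> "_CopyNumberEstimatorBase":
        """Estimate the 2-copy mixture weight from dual-colour counts.

        ``X`` is a :class:`DualColourCounts`; fractions are taken conditional
        on detection.  Sets ``two_copy_fraction_``, ``one_copy_fraction_``,
        ``ci_low_``, ``ci_high_``, ``out_of_model_`` and ``estimate_``.
        """
        counts = X
        n = counts.n_detected
        if n <= 0:
            raise ValueError("no detected complexes: cannot infer a copy-number mixture")
        d = counts.n_dual / n
        phi, out_of_model = self._invert(d)

        if self.ci_method == "wilson":
            d_lo, d_hi = _wilson_interval(counts.n_dual, n, self.confidence)
            ci_lo = self._invert(d_lo)[0]
            ci_hi = self._invert(d_hi)[0]
        elif self.ci_method == "bootstrap":
            rng = np.random.default_rng(self.random_state)
            probs = np.array([counts.n_dual, counts.n_A_only, counts.n_B_only], dtype=float) / n
            resampled = rng.multinomial(n, probs, size=self.n_boot)
            d_boot = resampled[:, 0] / n
            phi_boot = np.array([self._invert(db)[0] for db in d_boot])
            alpha = 1.0 - self.confidence
            ci_lo, ci_hi = np.quantile(phi_boot, [alpha / 2.0, 1.0 - alpha / 2.0])
        else:
            raise ValueError(f"unknown ci_method {self.ci_method!r}")

        self.two_copy_fraction_ = phi
        self.one_copy_fraction_ = 1.0 - phi
        self.ci_low_ = float(min(ci_lo, phi))
        self.ci_high_ = float(max(ci_hi, phi))
        self.out_of_model_ = out_of_model
        self.observed_dual_fraction_ = d
        self.estimate_ = CopyNumberEstimate(
            two_copy_fraction=phi,
            one_copy_fraction=1.0 - phi,
            ci_low=self.ci_low_,
            ci_high=self.ci_high_,
            observed_dual_fraction=d,
            n_detected=n,
            out_of_model=out_of_model,
            model=self._model_name,
        )
        return self


class SnapCopyNumberEstimator(_CopyNumberEstimatorBase):
    """Infer the 1-copy / 2-copy mixture of a SNAP-tagged protein.

    Parameters
    ----------
    p_label : per-polypeptide labelling efficiency (0.9 for the extended
        SNAP-labelling protocol).
    q_dyeA : probability a labelled polypeptide carries dye A; the dye batch
        ratio is tuned empirically toward 0.5.
    ci_method : "bootstrap" (multinomial over complexes, percentile interval)
        or "wilson" (score interval on the dual fraction, propagated).
    """

    _model_name = "binomial_snap"

    def __init__(self, p_label: float = 0.9, q_dyeA: float = 0.5,
                 ci_method: str = "bootstrap", n_boot: int = 1000,
                 confidence: float = 0.95, random_state: Optional[int] = 0):
        super().__init__(ci_method=ci_method, n_boot=n_boot,
                         confidence=confidence, random_state=random_state)
        self.p_label = p_label
        self.q_dyeA = q_dyeA

    def _invert(self, d: float) -> tuple[float, bool]:
        return _invert_snap(d, self.p_label, self.q_dyeA)

    def predict_dual_fraction(self, two_copy_fraction: float) -> float:
        """Forward model: expected detected-conditional dual fraction."""
        return snap_dual_fraction_mixture(two_copy_fraction, self.p_label, self.q_dyeA)


class RnaCopyNumberEstimator(_CopyNumberEstimatorBase):
    """Infer the 1-RNA / 2-RNA mixture of transported RNPs.

    Parameters
    ----------
    poisson_mean : mean number of body-incorporated dyes per RNA (~3 for the
        in vitro transcription protocol).
    colourA_fraction : fraction of RNA molecules from the colour-A preparation
        (0.5 for an equimolar mix).
    """

    _model_name = "poisson_body"

    def __init__(self, poisson_mean: float = 3.0, colourA_fraction: float = 0.5,
                 ci_method: str = "bootstrap", n_boot: int = 1000,
                 confidence: float = 0.95, random_state: Optional[int] = 0):
        super().__init__(ci_method=ci_method, n_boot=n_boot,
                         confidence=confidence, random_state=random_state)
        self.poisson_mean = poisson_mean
        self.colourA_fraction = colourA_fraction

    def _invert(self, d: float) -> tuple[float, bool]:
        return _invert_rna(d, self.poisson_mean, self.colourA_fraction)

    def predict_dual_fraction(self, two_rna_fraction: float) -> float:
        """Forward model: expected detected-conditional dual fraction."""
        return rna_dual_fraction(two_rna_fraction, self.poisson_mean, self.colourA_fraction)


def infer_two_copy_fraction(
    counts: DualColourCounts,
    p_label: float,
    q_dyeA: float = 0.5,
    ci_method: str = "bootstrap",
    n_boot: int = 1000,
    random_state: Optional[int] = 0,
) -> CopyNumberEstimate:
    """Functional wrapper over :class:`SnapCopyNumberEstimator`."""
    est = SnapCopyNumberEstimator(
        p_label=p_label, q_dyeA=q_dyeA, ci_method=ci_method,
        n_boot=n_boot, random_state=random_state,
    ).fit(counts)
    return est.estimate_


def infer_rna_mixture(
    counts: DualColourCounts,
    poisson_mean: float,
    colourA_fraction: float = 0.5,
    ci_method: str = "bootstrap",
    n_boot: int = 1000,
    random_state: Optional[int] = 0,
) -> CopyNumberEstimate:
    """Functional wrapper over :class:`RnaCopyNumberEstimator`."""
    est = RnaCopyNumberEstimator(
        poisson_mean=poisson_mean, colourA_fraction=colourA_fraction,
        ci_method=ci_method, n_boot=n_boot, random_state=random_state,
    ).fit(counts)
    return est.estimate_
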