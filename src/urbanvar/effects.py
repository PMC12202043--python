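"""Pairwise log-ratio effect sizes between two groups of posterior draws.

lnCVR compares coefficients of variation component by component, lnRR
compares marginal means, and lnRPT compares repeatabilities. All ratios are
formed draw by draw (pairing by MCMC iteration), which preserves the
posterior correlation between numerator and denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import DomainError, InsufficientDrawsError
from .partition import CVSummary

EFFECT_NAMES = ("lnCVR_P", "lnCVR_I", "lnCVR_R", "lnCVR_Y", "lnCVR_O", "lnRR", "lnRPT")


@dataclass
class EffectSize:
    name: str
    draws: np.ndarray
    median: float
    ci_low: float
    ci_high: float
    p_positive: float
    level: float = 0.95

    @property
    def evidence(self) -> bool:
        """True when the credible interval excludes zero."""
        return self.ci_low > 0 or self.ci_high < 0

    def to_dict(self) -> dict:
        fold, direction = fold_ratio(self.median)
        return {
            "effect": self.name,
            "median": self.median,
            "ci": [self.ci_low, self.ci_high],
            "level": self.level,
            "p_positive": self.p_positive,
            "evidence": self.evidence,
            "fold": fold,
            "direction": direction,
        }


def ln_ratio(numerator_draws: np.ndarray, denominator_draws: np.ndarray) -> np.ndarray:
    """Elementwise log(numerator/denominator), paired by draw index."""
    num = np.asarray(numerator_draws, dtype=float)
    den = np.asarray(denominator_draws, dtype=float)
    if num.shape != den.shape:
        from .errors import AlignmentError

        raise AlignmentError(
            f"draw streams differ in length: {num.shape} vs {den.shape}"
        )
    for label, arr in (("numerator", num), ("denominator", den)):
        bad = np.nonzero(arr <= 0)[0]
        if bad.size:
            raise DomainError(
                f"non-positive {label} draw at index {int(bad[0])}: {arr[bad[0]]}"
            )
    return np.log(num) - np.log(den)


def summarize(
    values: np.ndarray,
    level: float = 0.95,
    name: str = "effect",
    method: str = "quantile",
) -> EffectSize:
    """Median, credible interval and posterior sign probability.

    ``method`` is ``quantile`` (equal-tailed, default) or ``hpd`` (highest
    posterior density, computed over contiguous windows of sorted draws).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 100:
        raise InsufficientDrawsError(
            f"need >= 100 draws for a {level:.0%} interval, got {values.size}"
        )
    if method == "quantile":
        lo = float(np.quantile(values, (1 - level) / 2))
        hi = float(np.quantile(values, 1 - (1 - level) / 2))
    elif method == "hpd":
        srt = np.sort(values)
        m = int(np.ceil(level * srt.size))
        widths = srt[m - 1:] - srt[: srt.size - m + 1]
        i = int(np.argmin(widths))
        lo, hi = float(srt[i]), float(srt[i + m - 1])
    else:
        raise DomainError(f"unknown interval method {method!r}")
    return EffectSize(
        name=name,
        draws=values,
        median=float(np.median(values)),
        ci_low=lo,
        ci_high=hi,
        p_positive=float(np.mean(values > 0)),
        level=level,
    )


def _round_sig(x: float, sig: int) -> float:
    return float(f"{x:.{sig}g}")


def fold_ratio(ln_effect: float, sig_figs: int = 3) -> tuple[float, str]:
    """Fold change exp(|x|) (rounded to significant figures) and direction.

    Direction is ``"more"`` for positive log-effects, ``"less"`` for
    negative, and ``""`` at exactly zero (fold 1.0).
    """
    x = float(ln_effect)
    if not np.isfinite(x):
        raise DomainError(f"ln effect must be finite, got {x}")
    fold = _round_sig(float(np.exp(abs(x))), sig_figs)
    if x > 0:
        direction = "more"
    elif x < 0:
        direction = "less"
    else:
        direction = ""
    return fold, direction


def habitat_effect_sizes(
    summary: CVSummary,
    components_frame=None,
    numerator: str = "urban",
    denominator: str = "forest",
    level: float = 0.95,
    method: str = "quantile",
) -> dict[str, EffectSize]:
    """All pairwise effect sizes from a per-draw CV summary.

    Produces lnCVR_P, lnCVR_I (and lnCVR_R when present), lnRR and lnRPT.
    When the per-draw components table is supplied, lnCVR_Y and lnCVR_O are
    added for heterogeneous year/observer variances (CV_x = sqrt(V_x)/mean).
    """
    num = summary.for_group(numerator)
    den = summary.for_group(denominator)
    out: dict[str, EffectSize] = {}
    pairs = [("lnCVR_P", "CV_P"), ("lnCVR_I", "CV_I")]
    if "CV_R" in num.columns:
        pairs.append(("lnCVR_R", "CV_R"))
    for name, col in pairs:
        stream = ln_ratio(num[col].to_numpy(), den[col].to_numpy())
        out[name] = summarize(stream, level=level, name=name, method=method)
    out["lnRR"] = summarize(
        ln_ratio(num["mean"].to_numpy(), den["mean"].to_numpy()),
        level=level, name="lnRR", method=method,
    )
    out["lnRPT"] = summarize(
        ln_ratio(num["rpt"].to_numpy(), den["rpt"].to_numpy()),
        level=level, name="lnRPT", method=method,
    )
    if components_frame is not None:
        comp_num = components_frame[components_frame["group"] == numerator]
        comp_den = components_frame[components_frame["group"] == denominator]
        for name, col in (("lnCVR_Y", "V_y"), ("lnCVR_O", "V_o")):
            vn = comp_num.sort_values("draw")[col].to_numpy()
            vd = comp_den.sort_values("draw")[col].to_numpy()
            if np.all(vn > 0) and np.all(vd > 0) and not np.allclose(vn, vd):
                cv_n = np.sqrt(vn) / num["mean"].to_numpy()
                cv_d = np.sqrt(vd) / den["mean"].to_numpy()
                out[name] = summarize(
                    ln_ratio(cv_n, cv_d), level=level, name=name, method=method
                )
    return out


def effects_report(effects: Mapping[str, EffectSize]) -> list[dict]:
    """JSON-ready list of effect-size dictionaries."""
    return [effects[name].to_dict() for name in effects]
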