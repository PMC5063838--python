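"""Detection scoring: matching, confusion counts, and the noise benchmark.

Circle detection has no true negatives — a circle is correctly found
(TP), spuriously reported (FP) or missed (FN). Derived rates:

    precision = PPV = 100 * TP / (TP + FP)
    sensitivity = TPR = 100 * TP / (TP + FN)
    FDR = 100 * FP / (TP + FP)
    FPR = 100 * FP / n_truth          (expert-count denominator)

The FPR convention divides false positives by the number of expert-
confirmed cells rather than by a negative class, which does not exist
here; a 'standard' toggle reports FPR as undefined instead. Undefined
ratios (zero denominators) are always reported as None, never 0 or 100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circle import CircleParams
from .config import RunConfig
from .detector import detect
from .synthetic import NoiseSpec, generate_suite

__all__ = ["MatchResult", "EvalReport", "match", "report", "noise_bench",
           "evaluate_suite"]


@dataclass(frozen=True)
class MatchResult:
    """One-to-one detection/truth assignment with confusion counts."""

    pairs: tuple[tuple[int, int], ...]   # (detection index, truth index)
    tp: int
    fp: int
    fn: int


@dataclass(frozen=True)
class EvalReport:
    tp: int
    fp: int
    fn: int
    precision_pct: float | None
    sensitivity_pct: float | None
    tpr_pct: float | None
    fpr_pct: float | None
    fdr_pct: float | None
    ppv_pct: float | None

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn,
            "precision_pct": self.precision_pct,
            "sensitivity_pct": self.sensitivity_pct,
            "tpr_pct": self.tpr_pct, "fpr_pct": self.fpr_pct,
            "fdr_pct": self.fdr_pct, "ppv_pct": self.ppv_pct,
        }


def match(
    detections: list[CircleParams],
    truths: list[CircleParams],
    tau_c: float = 5.0,
    tau_r: float = 0.2,
) -> MatchResult:
    """Greedy one-to-one matching in ascending centre-distance order.

    A (detection, truth) pair is admissible iff the centre distance is
    <= ``tau_c`` px and the radius error is <= ``tau_r`` * truth radius.
    Deterministic: ties in distance break on (detection, truth) index.
    """
    if tau_c <= 0 or not (0.0 < tau_r < 1.0):
        raise ValueError("tau_c must be > 0 and tau_r in (0, 1)")
    candidates = []
    for i, d in enumerate(detections):
        for j, t in enumerate(truths):
            dist = float(np.hypot(d.x0 - t.x0, d.y0 - t.y0))
            if dist <= tau_c and abs(d.r - t.r) <= tau_r * t.r:
                candidates.append((dist, i, j))
    candidates.sort()
    used_d: set[int] = set()
    used_t: set[int] = set()
    pairs = []
    for _, i, j in candidates:
        if i in used_d or j in used_t:
            continue
        pairs.append((i, j))
        used_d.add(i)
        used_t.add(j)
    tp = len(pairs)
    return MatchResult(pairs=tuple(pairs), tp=tp,
                       fp=len(detections) - tp, fn=len(truths) - tp)


def _ratio(num: int, den: int) -> float | None:
    if den <= 0:
        warnings.warn("undefined ratio (zero denominator) reported as null",
                      stacklevel=3)
        return None
    return 100.0 * num / den


def report(m: MatchResult, n_truth: int | None = None,
           fpr_definition: str = "expert") -> EvalReport:
    """Derive the rate table from confusion counts.

    ``n_truth`` defaults to TP + FN. With the 'standard' FPR definition
    the rate is reported as undefined (no true negatives exist).
    """
    if min(m.tp, m.fp, m.fn) < 0:
        raise ValueError("counts must be non-negative")
    if n_truth is None:
        n_truth = m.tp + m.fn
    precision = _ratio(m.tp, m.tp + m.fp)
    sensitivity = _ratio(m.tp, m.tp + m.fn)
    fdr = _ratio(m.fp, m.tp + m.fp)
    if fpr_definition == "expert":
        fpr = _ratio(m.fp, n_truth)
    else:
        warnings.warn("standard FPR requires true negatives; reporting null",
                      stacklevel=2)
        fpr = None
    return EvalReport(tp=m.tp, fp=m.fp, fn=m.fn,
                      precision_pct=precision, sensitivity_pct=sensitivity,
                      tpr_pct=sensitivity, fpr_pct=fpr, fdr_pct=fdr,
                      ppv_pct=precision)


def evaluate_suite(
    suite,
    config: RunConfig,
    seed: int = 0,
) -> EvalReport:
    """Detect on every (image, truth) pair of a suite and pool the counts."""
    ev = config.eval
    tp = fp = fn = 0
    master = np.random.default_rng(seed)
    for img, truth in suite:
        res = detect(img, config=config, seed=int(master.integers(2**31)))
        m = match(res.circles, list(truth.circles),
                  tau_c=ev.tau_c, tau_r=ev.tau_r)
        tp += m.tp
        fp += m.fp
        fn += m.fn
    pooled = MatchResult(pairs=(), tp=tp, fp=fp, fn=fn)
    return report(pooled, fpr_definition=ev.fpr_definition)


#: Corruption levels of the noise benchmark: clean baseline, Gaussian
#: sigma = 10 and 15, salt-and-pepper 10 % and 15 %.
NOISE_LEVELS: tuple[tuple[str, NoiseSpec], ...] = (
    ("clean", NoiseSpec()),
    ("gaussian_sigma10", NoiseSpec(kind="gaussian", sigma=10.0)),
    ("gaussian_sigma15", NoiseSpec(kind="gaussian", sigma=15.0)),
    ("salt_pepper_10pct", NoiseSpec(kind="salt_pepper", fraction=0.10)),
    ("salt_pepper_15pct", NoiseSpec(kind="salt_pepper", fraction=0.15)),
)


def noise_bench(
    config: RunConfig,
    n_per_level: int = 10,
    seed: int = 0,
    levels=NOISE_LEVELS,
) -> pd.DataFrame:
    """Detection quality across corruption levels of the same base scenes.

    Every level reuses the same underlying clean suite (per-image seeds
    derive from ``seed``) so rows differ only in the corruption applied.
    Returns one row per level: counts plus TPR/FPR/FDR/PPV.
    """
    rows = []
    for name, noise in levels:
        suite = generate_suite(n_per_level, profile="clean", seed=seed,
                               noise=noise)
        rep = evaluate_suite(suite, config, seed=seed + 1)
        rows.append({"level": name, **rep.to_dict()})
    return pd.DataFrame(rows)
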