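"""The eleven-metric battery: intensity-difference, information-theoretic and
conditional-statistics similarity measures between a reference image R and a
candidate image S, plus their normalization into [0,1] scores with 1 optimal.

Raw values follow the canonical definitions; because the raw metrics live on
incommensurable scales (a mean-squared difference versus an entropy versus a
correlation), every metric additionally gets a *score* mapped into [0,1] with
1 optimal, so that an n-candidate evaluation yields a directly comparable
n x 11 table.  The score mappings (documented per function) are this
package's own convention; out-of-range raws are clamped.

Metric columns appear everywhere in the fixed order :data:`METRIC_ORDER`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .imaging import (
    DEFAULT_BINS,
    ConditionalStats,
    Image,
    conditional_stats,
    entropy,
    joint_histogram,
    marginal_histogram,
    shared_range,
)

logger = logging.getLogger(__name__)

__all__ = [
    "METRIC_ORDER",
    "METRIC_DIRECTIONS",
    "MetricResult",
    "MetricTable",
    "BatteryConfig",
    "MetricBattery",
    "DegenerateInputError",
    "msd",
    "adi",
    "edi",
    "mi_family",
    "ncc",
    "cor",
    "woo",
    "compute_all",
    "evaluate_battery",
]

#: Fixed column order of the battery.
METRIC_ORDER: Tuple[str, ...] = (
    "msd", "adi", "edi", "mif", "nmi", "ncc", "cor", "woo", "red", "uni", "aum",
)

#: Whether the *raw* value is a distance (smaller better) or similarity (larger better).
METRIC_DIRECTIONS: Dict[str, str] = {
    "msd": "distance",
    "adi": "distance",
    "edi": "distance",
    "mif": "similarity",
    "nmi": "similarity",
    "ncc": "similarity",
    "cor": "similarity",
    "woo": "similarity",
    "red": "similarity",
    "uni": "distance",
    "aum": "distance",
}


class DegenerateInputError(ValueError):
    """Raised when a metric is undefined for the given pair (e.g. constant image)."""


@dataclass
class MetricResult:
    metric_name: str
    raw_value: float
    score: float
    direction: str
    degenerate: bool = False
    info: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isnan(self.score) and not 0.0 <= self.score <= 1.0:
            raise ValueError(f"{self.metric_name}: score {self.score} outside [0,1]")


def _clamp(x: float, name: str) -> float:
    if x < 0.0 or x > 1.0:
        logger.warning("%s score %.6g clamped to [0,1]", name, x)
    return float(min(max(x, 0.0), 1.0))


def _check_shapes(r: Image, s: Image) -> None:
    if r.shape != s.shape:
        raise ValueError(f"shape mismatch: reference {r.shape} vs candidate {s.shape}")


def _dynamic_range(r: Image, s: Image) -> float:
    lo, hi = shared_range(r, s)
    return hi - lo


def msd(r: Image, s: Image, mask: Optional[np.ndarray] = None) -> MetricResult:
    """Mean squared intensity difference; score = 1 - raw / D^2 with D the
    shared dynamic range of the pair (so raw = D^2, the worst possible
    voxelwise disagreement, maps to 0)."""
    _check_shapes(r, s)
    d = r.ravel(mask) - s.ravel(mask)
    raw = float(np.mean(d**2))
    dr = _dynamic_range(r, s)
    score = 1.0 if raw == 0.0 else _clamp(1.0 - raw / dr**2, "msd")
    return MetricResult("msd", raw, score, "distance")


def adi(r: Image, s: Image, mask: Optional[np.ndarray] = None) -> MetricResult:
    """Mean absolute intensity difference; score = 1 - raw / D."""
    _check_shapes(r, s)
    d = r.ravel(mask) - s.ravel(mask)
    raw = float(np.mean(np.abs(d)))
    dr = _dynamic_range(r, s)
    score = 1.0 if raw == 0.0 else _clamp(1.0 - raw / dr, "adi")
    return MetricResult("adi", raw, score, "distance")


def edi(
    r: Image, s: Image, bins: int = DEFAULT_BINS, mask: Optional[np.ndarray] = None
) -> MetricResult:
    """Shannon entropy (bits) of the binned difference-image distribution.

    A perfectly reproduced candidate gives a constant (zero) difference image
    and hence zero entropy; a structureless difference spread uniformly over
    all bins attains the maximum log2(bins).  score = 1 - raw / log2(bins).
    """
    _check_shapes(r, s)
    diff = Image(r.voxels - s.voxels)
    if diff.is_constant:
        return MetricResult("edi", 0.0, 1.0, "distance")
    hist = marginal_histogram(diff, bins=bins, mask=mask)
    raw = entropy(hist)
    hmax = np.log2(bins) if bins > 1 else 1.0
    return MetricResult("edi", raw, _clamp(1.0 - raw / hmax, "edi"), "distance")


def mi_family(
    r: Image,
    s: Image,
    bins: Tuple[int, int] = (DEFAULT_BINS, DEFAULT_BINS),
    mask: Optional[np.ndarray] = None,
) -> Dict[str, MetricResult]:
    """The five joint-histogram metrics {mif, nmi, red, uni, aum} from one joint.

    With marginal entropies H_R, H_S, joint entropy H_RS and mutual
    information I = H_R + H_S - H_RS (clamped at 0):

    ======  =====================  ==========================
    metric  raw                    score
    ======  =====================  ==========================
    mif     I                      I / min(H_R, H_S)
    nmi     I / H_RS + 1           raw - 1
    red     I / (H_R + H_S)        2 * raw
    uni     1 - I / H_RS           1 - raw
    aum     1 - I / max(H_R, H_S)  1 - raw
    ======  =====================  ==========================

    Degenerate pairs (a constant image has zero marginal entropy) are flagged;
    two constant images score 1 on all five if voxelwise identical, else 0.
    """
    _check_shapes(r, s)
    if r.is_constant and s.is_constant:
        identical = bool(np.array_equal(r.voxels, s.voxels))
        sc = 1.0 if identical else 0.0
        return {
            name: MetricResult(name, float("nan"), sc, METRIC_DIRECTIONS[name], degenerate=True)
            for name in ("mif", "nmi", "red", "uni", "aum")
        }
    jh = joint_histogram(r, s, bins=bins, mask=mask)
    h_r = entropy(jh.marginal_r())
    h_s = entropy(jh.marginal_s())
    h_rs = entropy(jh)
    i_rs = max(h_r + h_s - h_rs, 0.0)
    degenerate = h_r == 0.0 or h_s == 0.0  # one image constant (under this binning)

    h_min, h_max = min(h_r, h_s), max(h_r, h_s)
    out: Dict[str, MetricResult] = {}
    out["mif"] = MetricResult(
        "mif",
        i_rs,
        _clamp(i_rs / h_min, "mif") if h_min > 0 else 0.0,
        "similarity",
        degenerate=degenerate,
        info={"H_R": h_r, "H_S": h_s, "H_RS": h_rs},
    )
    nmi_raw = i_rs / h_rs + 1.0 if h_rs > 0 else float("nan")
    out["nmi"] = MetricResult(
        "nmi",
        nmi_raw,
        _clamp(nmi_raw - 1.0, "nmi") if h_rs > 0 else 0.0,
        "similarity",
        degenerate=degenerate,
    )
    red_raw = i_rs / (h_r + h_s) if h_r + h_s > 0 else float("nan")
    out["red"] = MetricResult(
        "red",
        red_raw,
        _clamp(2.0 * red_raw, "red") if h_r + h_s > 0 else 0.0,
        "similarity",
        degenerate=degenerate,
    )
    uni_raw = 1.0 - i_rs / h_rs if h_rs > 0 else float("nan")
    out["uni"] = MetricResult(
        "uni",
        uni_raw,
        _clamp(1.0 - uni_raw, "uni") if h_rs > 0 else 0.0,
        "distance",
        degenerate=degenerate,
    )
    aum_raw = 1.0 - i_rs / h_max if h_max > 0 else float("nan")
    out["aum"] = MetricResult(
        "aum",
        aum_raw,
        _clamp(1.0 - aum_raw, "aum") if h_max > 0 else 0.0,
        "distance",
        degenerate=degenerate,
    )
    return out


def ncc(r: Image, s: Image, mask: Optional[np.ndarray] = None) -> MetricResult:
    """Normalized cross-correlation (Pearson, population moments over the whole
    image); raw in [-1, 1], score = (raw + 1) / 2."""
    _check_shapes(r, s)
    rv, sv = r.ravel(mask), s.ravel(mask)
    sr, ss = float(rv.std()), float(sv.std())
    if sr == 0.0 or ss == 0.0:
        raise DegenerateInputError("ncc undefined: constant image (zero variance)")
    raw = float(np.mean((rv - rv.mean()) * (sv - sv.mean())) / (sr * ss))
    raw = min(max(raw, -1.0), 1.0)
    return MetricResult("ncc", raw, (raw + 1.0) / 2.0, "similarity")


def cor(
    r: Image, s: Image, bins: Optional[int] = None, mask: Optional[np.ndarray] = None
) -> MetricResult:
    """Correlation ratio: 1 - mean conditional variance of S given R's
    intensity level, over S's global variance.  1 means S is a deterministic
    function of R's level; 0 means knowing R's level says nothing about S.

    By default conditioning is on exact distinct intensity values of R; pass
    ``bins`` to condition on equal-width bins instead.  score = raw (clamped).
    """
    _check_shapes(r, s)
    cs = conditional_stats(r, s, bins=bins, mask=mask)
    if cs.global_var == 0.0:
        raise DegenerateInputError("cor undefined: candidate image is constant")
    raw = 1.0 - float(np.sum(cs.counts * cs.var)) / (cs.n * cs.global_var)
    return MetricResult("cor", raw, _clamp(raw, "cor"), "similarity")


def woo(
    r: Image,
    s: Image,
    bins: Optional[int] = None,
    eps: float = 1e-8,
    mask: Optional[np.ndarray] = None,
) -> MetricResult:
    """Woods criterion: 1 minus the count-weighted mean coefficient of
    variation sigma(i)/mu(i) of S within each intensity level of R.

    Levels whose |mu(i)| <= eps are skipped (a coefficient of variation is
    meaningless around zero mean); the number skipped is recorded in
    ``info['skipped_levels']``.  score = raw clamped to [0,1].
    """
    _check_shapes(r, s)
    cs = conditional_stats(r, s, bins=bins, mask=mask)
    keep = np.abs(cs.mean) > eps
    if not np.any(keep):
        raise DegenerateInputError("woo undefined: all conditioning levels have |mu| <= eps")
    raw = 1.0 - float(np.sum(cs.counts[keep] * cs.std[keep] / cs.mean[keep])) / cs.n
    skipped = int(np.sum(~keep))
    return MetricResult(
        "woo", raw, _clamp(raw, "woo"), "similarity",
        info={"skipped_levels": float(skipped)},
    )


@dataclass
class BatteryConfig:
    """Settings shared by all metrics in one battery evaluation."""

    bins: int = DEFAULT_BINS                 # marginal / joint histogram bins
    diff_bins: int = DEFAULT_BINS            # difference-image bins for edi
    cond_bins: Optional[int] = None          # None = exact-value conditioning (cor/woo)
    eps: float = 1e-8                        # Woods zero-mean guard
    background: Optional[float] = None       # mask out reference voxels equal to this

    def mask_for(self, r: Image) -> Optional[np.ndarray]:
        if self.background is None:
            return None
        return r.voxels != self.background


def compute_all(
    r: Image, s: Image, config: Optional[BatteryConfig] = None
) -> Dict[str, MetricResult]:
    """All 11 metrics of one (reference, candidate) pair, keyed by metric name.

    Metrics that are undefined for the pair come back as NaN-valued results
    flagged degenerate rather than raising.
    """
    config = config or BatteryConfig()
    mask = config.mask_for(r)
    results: Dict[str, MetricResult] = {}
    results["msd"] = msd(r, s, mask=mask)
    results["adi"] = adi(r, s, mask=mask)
    results["edi"] = edi(r, s, bins=config.diff_bins, mask=mask)
    results.update(mi_family(r, s, bins=(config.bins, config.bins), mask=mask))
    for name, fn, kwargs in (
        ("ncc", ncc, {}),
        ("cor", cor, {"bins": config.cond_bins}),
        ("woo", woo, {"bins": config.cond_bins, "eps": config.eps}),
    ):
        try:
            results[name] = fn(r, s, mask=mask, **kwargs)
        except DegenerateInputError as exc:
            logger.warning("%s degenerate for candidate: %s", name, exc)
            results[name] = MetricResult(
                name, float("nan"), float("nan"), METRIC_DIRECTIONS[name], degenerate=True
            )
    return {name: results[name] for name in METRIC_ORDER}


@dataclass
class MetricTable:
    """The n x p table of battery results: one row per candidate, one column
    per metric (fixed order), scores in [0,1] with raw values alongside.
    Undefined cells are NaN, never fabricated."""

    scores: pd.DataFrame
    raws: pd.DataFrame
    degenerate: pd.DataFrame

    @property
    def n(self) -> int:
        return len(self.scores)

    @property
    def p(self) -> int:
        return self.scores.shape[1]

    @property
    def candidate_ids(self) -> List[str]:
        return list(self.scores.index)

    def to_csv(self, scores_path, raws_path=None) -> None:
        self.scores.to_csv(scores_path, index_label="candidate_id")
        if raws_path is not None:
            self.raws.to_csv(raws_path, index_label="candidate_id")

    @classmethod
    def from_csv(cls, scores_path, raws_path=None) -> "MetricTable":
        scores = pd.read_csv(scores_path, index_col="candidate_id")
        scores.index = scores.index.astype(str)
        if raws_path is not None:
            raws = pd.read_csv(raws_path, index_col="candidate_id")
            raws.index = raws.index.astype(str)
        else:
            raws = pd.DataFrame(np.nan, index=scores.index, columns=scores.columns)
        return cls(scores=scores, raws=raws, degenerate=scores.isna())

    @classmethod
    def from_results(
        cls, rows: Sequence[Dict[str, MetricResult]], ids: Sequence[str]
    ) -> "MetricTable":
        cols = list(METRIC_ORDER)
        scores = pd.DataFrame(
            [[row[m].score for m in cols] for row in rows], index=list(ids), columns=cols
        )
        raws = pd.DataFrame(
            [[row[m].raw_value for m in cols] for row in rows], index=list(ids), columns=cols
        )
        degen = pd.DataFrame(
            [[row[m].degenerate for m in cols] for row in rows], index=list(ids), columns=cols
        )
        return cls(scores=scores, raws=raws, degenerate=degen)


def evaluate_battery(
    r: Image,
    candidates: Sequence[Image],
    ids: Optional[Sequence[str]] = None,
    config: Optional[BatteryConfig] = None,
) -> MetricTable:
    """Evaluate every candidate against the reference under all 11 metrics."""
    if len(candidates) < 1:
        raise ValueError("need at least one candidate image")
    if ids is None:
        ids = [f"candidate/{i:04d}" for i in range(len(candidates))]
    if len(ids) != len(candidates):
        raise ValueError("ids and candidates differ in length")
    rows = []
    for cid, s in zip(ids, candidates):
        if s.shape != r.shape:
            raise ValueError(
                f"candidate {cid!r}: shape mismatch reference {r.shape} vs {s.shape}"
            )
        rows.append(compute_all(r, s, config))
    return MetricTable.from_results(rows, ids)


class MetricBattery(BaseEstimator, TransformerMixin):
    """Scikit-learn style transformer: fit on a reference image, transform a
    list of candidate images into their (n, 11) score table.

    Parameters mirror :class:`BatteryConfig`.  Fitted attributes:

    reference_ : Image
        The reference all candidates are compared against.
    metric_names_ : tuple of str
        Column order of the transformed output.
    """

    def __init__(
        self,
        bins: int = DEFAULT_BINS,
        diff_bins: int = DEFAULT_BINS,
        cond_bins: Optional[int] = None,
        eps: float = 1e-8,
        background: Optional[float] = None,
    ):
        self.bins = bins
        self.diff_bins = diff_bins
        self.cond_bins = cond_bins
        self.eps = eps
        self.background = background

    def _config(self) -> BatteryConfig:
        return BatteryConfig(
            bins=self.bins,
            diff_bins=self.diff_bins,
            cond_bins=self.cond_bins,
            eps=self.eps,
            background=self.background,
        )

    def fit(self, X: Union[Image, np.ndarray], y=None) -> "MetricBattery":
        """X is the reference image (an Image or a bare voxel array)."""
        self.reference_ = X if isinstance(X, Image) else Image(np.asarray(X))
        self.metric_names_ = METRIC_ORDER
        return self

    def evaluate(
        self, candidates: Sequence[Image], ids: Optional[Sequence[str]] = None
    ) -> MetricTable:
        """Full battery output (scores + raws + degenerate flags)."""
        if not hasattr(self, "reference_"):
            raise RuntimeError("MetricBattery must be fit on a reference image first")
        return evaluate_battery(self.reference_, candidates, ids=ids, config=self._config())

    def transform(self, X: Sequence[Image]) -> pd.DataFrame:
        """Score table for a sequence of candidate images."""
        return self.evaluate(list(X)).scores
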