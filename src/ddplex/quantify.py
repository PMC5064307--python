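"""Absolute quantification of multiplexed targets by Poisson partition statistics.

Each droplet is an independent sub-reaction; with mean lambda target copies
per droplet, the fraction of positive droplets is p = 1 - exp(-lambda), so

    lambda = -ln(1 - p_hat),    p_hat = positives / accepted droplets,

and the concentration follows from the droplet volume (0.85 nL by default):
copies/uL = lambda / V_droplet, copies/reaction = copies/uL x 20 uL.

Confidence intervals: a Wilson score interval on p_hat is transformed
through the (monotone) Poisson link, which behaves well at extreme counts
(0 positives gives a lower bound of exactly 0, a saturated well an infinite
upper bound). A plain normal-approximation interval is available as an
alternative strategy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal

from statsmodels.stats.proportion import proportion_confint

from .clustering import ClusterGrid

__all__ = [
    "Target",
    "AssayLayout",
    "QuantConfig",
    "TargetResult",
    "positive_cells",
    "count_combinations",
    "estimate_target",
    "quantify_multiplex",
    "example_tetraplex",
]


@dataclass(frozen=True)
class Target:
    """One assay target: its name, fluorescence channel and amplitude level."""

    name: str
    channel: int  # 1 or 2
    level: str  # "low" or "high"

    def __post_init__(self) -> None:
        if self.channel not in (1, 2):
            raise ValueError(f"target {self.name!r}: channel must be 1 or 2")
        if self.level not in ("low", "high"):
            raise ValueError(f"target {self.name!r}: level must be 'low' or 'high'")


@dataclass(frozen=True)
class AssayLayout:
    """Binding of up to four targets to (channel, amplitude level) slots.

    At most two targets per channel and each (channel, level) slot is unique;
    a full 4-plex occupies all four slots.
    """

    targets: tuple[Target, ...]
    assay_name: str = "assay"

    def __post_init__(self) -> None:
        targets = tuple(self.targets)
        if not 1 <= len(targets) <= 4:
            raise ValueError("layout must bind between 1 and 4 targets")
        names = [t.name for t in targets]
        if len(set(names)) != len(names):
            raise ValueError("target names must be unique")
        slots = [(t.channel, t.level) for t in targets]
        if len(set(slots)) != len(slots):
            raise ValueError("each (channel, level) slot may hold only one target")
        for ch in (1, 2):
            if sum(t.channel == ch for t in targets) > 2:
                raise ValueError(f"channel {ch} holds more than 2 targets")
        object.__setattr__(self, "targets", targets)

    def targets_on_channel(self, channel: int) -> tuple[Target, ...]:
        return tuple(t for t in self.targets if t.channel == channel)

    def target(self, name: str) -> Target:
        for t in self.targets:
            if t.name == name:
                return t
        raise KeyError(f"no target named {name!r} in layout {self.assay_name!r}")

    def n_bands(self, channel: int) -> int:
        n = len(self.targets_on_channel(channel))
        return {0: 1, 1: 2, 2: 4}[n]


def example_tetraplex() -> AssayLayout:
    """Illustrative 4-plex layout shaped like the MTQ1 GMO maize assay.

    Binds the maize endogene hmgA and three GM events; the channel/level
    assignment here is illustrative, not an assay specification.
    """
    return AssayLayout(
        targets=(
            Target("hmgA", channel=1, level="high"),
            Target("MON863", channel=1, level="low"),
            Target("MON810", channel=2, level="high"),
            Target("DP98140", channel=2, level="low"),
        ),
        assay_name="MTQ1-like",
    )


@dataclass(frozen=True)
class QuantConfig:
    """Quantification settings.

    droplet_volume_nL: partition volume, default 0.85 nL.
    reaction_volume_uL: reaction scale for copies-per-reaction, default 20 uL.
    ci_level: two-sided confidence level for the concentration interval.
    detection_min_droplets: positive droplets needed to call a target
        detected (default 3).
    ci_method: "wilson" (default) or "normal".
    """

    droplet_volume_nL: float = 0.85
    reaction_volume_uL: float = 20.0
    ci_level: float = 0.95
    detection_min_droplets: int = 3
    ci_method: Literal["wilson", "normal"] = "wilson"

    def __post_init__(self) -> None:
        if self.droplet_volume_nL <= 0:
            raise ValueError("droplet_volume_nL must be positive")
        if self.reaction_volume_uL <= 0:
            raise ValueError("reaction_volume_uL must be positive")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must lie strictly between 0 and 1")
        if self.detection_min_droplets < 1:
            raise ValueError("detection_min_droplets must be at least 1")
        if self.ci_method not in ("wilson", "normal"):
            raise ValueError(f"unknown ci_method {self.ci_method!r}")

    @property
    def droplet_volume_uL(self) -> float:
        return self.droplet_volume_nL / 1000.0


@dataclass(frozen=True)
class TargetResult:
    """Quantification result for one target in one well."""

    well_id: str
    target_name: str
    positives: int
    total: int
    p_hat: float
    lambda_: float
    copies_per_uL: float
    copies_per_reaction: float
    ci_low: float
    ci_high: float
    detected: bool
    saturated: bool


def positive_cells(layout: AssayLayout, target_name: str) -> set[tuple[int, int]]:
    """Grid cells in which the named target is present.

    A droplet is positive for a target when its band on the target's channel
    contains that target: bands {1, 3} for the low-amplitude target, {2, 3}
    for the high one (band 3 is the same-channel double positive), or band
    {1} on a channel carrying a single target. The other axis is free, so a
    4-plex target is positive in exactly 8 of the 16 cells.
    """
    target = layout.target(target_name)
    n_own = layout.n_bands(target.channel)
    if n_own == 4:
        own_bands = {1, 3} if target.level == "low" else {2, 3}
    else:
        own_bands = {1}
    other_channel = 2 if target.channel == 1 else 1
    other_bands = range(layout.n_bands(other_channel))
    if target.channel == 1:
        return {(i, j) for i in own_bands for j in other_bands}
    return {(i, j) for j in own_bands for i in other_bands}


def count_combinations(n_targets: int) -> int:
    """Number of distinct positive target-presence combinations.

    ``n`` targets give 2**n droplet clusters, of which 2**n - 1 contain at
    least one target (a 4-plex has 15 positive clusters plus the negatives).
    """
    if n_targets < 1:
        raise ValueError("n_targets must be at least 1")
    if n_targets > 8:
        raise ValueError("n_targets above 8 is not supported")
    return 2**n_targets - 1


def _interval_on_p(
    positives: int, total: int, config: QuantConfig
) -> tuple[float, float]:
    method = {"wilson": "wilson", "normal": "normal"}[config.ci_method]
    low, high = proportion_confint(
        positives, total, alpha=1 - config.ci_level, method=method
    )
    return max(0.0, float(low)), min(1.0, float(high))


def estimate_target(
    positives: int,
    total: int,
    config: QuantConfig | None = None,
    target_name: str = "target",
    well_id: str = "well",
) -> TargetResult:
    """Poisson estimate of one target's concentration from droplet counts.

    Parameters
    ----------
    positives, total
        Positive and accepted droplet counts (0 <= positives <= total,
        total >= 1).

    Notes
    -----
    A saturated well (all droplets positive) yields infinite ``lambda_`` and
    copy estimates and an infinite upper bound; it is flagged via
    ``saturated`` rather than raising, so real plates containing saturated
    wells can still be reported.
    """
    config = config or QuantConfig()
    if total < 1:
        raise ValueError("total droplet count must be at least 1")
    if not 0 <= positives <= total:
        raise ValueError(f"positives {positives} outside [0, total={total}]")

    p_hat = positives / total
    scale = config.reaction_volume_uL / config.droplet_volume_uL
    saturated = positives == total
    lam = math.inf if saturated else -math.log1p(-p_hat)
    copies_per_uL = lam / config.droplet_volume_uL
    copies_per_reaction = lam * scale if not saturated else math.inf

    p_low, p_high = _interval_on_p(positives, total, config)
    ci_low = -math.log1p(-p_low) * scale
    ci_high = math.inf if p_high >= 1.0 else -math.log1p(-p_high) * scale

    return TargetResult(
        well_id=well_id,
        target_name=target_name,
        positives=int(positives),
        total=int(total),
        p_hat=p_hat,
        lambda_=lam,
        copies_per_uL=copies_per_uL,
        copies_per_reaction=copies_per_reaction,
        ci_low=ci_low,
        ci_high=ci_high,
        detected=positives >= config.detection_min_droplets,
        saturated=saturated,
    )


def quantify_multiplex(
    grid: ClusterGrid,
    layout: AssayLayout,
    config: QuantConfig | None = None,
    well_id: str = "well",
) -> list[TargetResult]:
    """Quantify every target of a layout from a classified cluster grid.

    For each target, the positive count is the sum of droplet counts over
    its positive cells; results follow layout order.
    """
    config = config or QuantConfig()
    if grid.total < 1:
        raise ValueError("cluster grid holds no droplets")
    expected = (layout.n_bands(1), layout.n_bands(2))
    if grid.counts.shape != expected:
        raise ValueError(
            f"cluster grid shape {grid.counts.shape} does not match layout "
            f"band structure {expected}"
        )
    results = []
    for target in layout.targets:
        cells = positive_cells(layout, target.name)
        positives = int(sum(grid.counts[i, j] for i, j in cells))
        results.append(
            estimate_target(positives, grid.total, config, target.name, well_id)
        )
    return results
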