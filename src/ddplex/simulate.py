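"""Synthetic two-channel droplet generator with ground-truth occupancy.

The generator emulates the measurement process that amplitude-multiplexed
droplet analysis assumes:

* target copies per droplet are Poisson with mean lambda derived from the
  configured copies per reaction and the droplet volume;
* a droplet's channel amplitude is a baseline plus the amplitude increments
  of the same-channel targets it contains (end-point chemistry: presence,
  not copy count, sets the level; increments add, putting the
  double-positive cluster above both single-positive clusters) plus
  Gaussian cluster noise;
* an optional fraction of positive droplets is rendered as "rain": on each
  channel where such a droplet is positive, its amplitude is drawn
  uniformly between the baseline and its full cluster mean, reproducing the
  intermediate-amplitude artifact that can fake positives for the
  low-amplitude target.

Every simulated well carries a :class:`GroundTruth` with per-droplet copy
numbers, true bands and rain labels, so classification and quantification
can be scored against a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import IO, Mapping, Sequence

import numpy as np

from .clustering import SeparationGrid, classify
from .io import DropletSet
from .quantify import AssayLayout, QuantConfig, quantify_multiplex

__all__ = [
    "ChannelModel",
    "SimulationConfig",
    "GroundTruth",
    "DilutionLevel",
    "lambda_from_copies",
    "theoretical_grid",
    "simulate_well",
    "simulate_dilution_series",
    "write_ground_truth",
    "write_amplitude_csv",
]


@dataclass(frozen=True)
class ChannelModel:
    """Amplitude model of one fluorescence channel.

    Defaults (baseline 800 +/- 60, increments 2200/4800, cluster sd 150
    arbitrary units) are instrument-like fixture values, not calibration
    data: amplitude scales vary with probe batch and reader calibration.
    """

    baseline_mean: float = 800.0
    baseline_sd: float = 60.0
    low_increment: float = 2200.0
    high_increment: float = 4800.0
    cluster_sd: float = 150.0

    def __post_init__(self) -> None:
        if self.baseline_sd <= 0 or self.cluster_sd <= 0:
            raise ValueError("baseline_sd and cluster_sd must be positive")
        if self.low_increment <= 0 or self.high_increment <= 0:
            raise ValueError("low_increment and high_increment must be positive")
        if self.high_increment <= self.low_increment:
            raise ValueError("high_increment must exceed low_increment")

    def increment(self, level: str) -> float:
        return self.low_increment if level == "low" else self.high_increment


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth concentrations plus the amplitude/noise/rain model.

    ``copies_per_reaction`` maps target names (matching an
    :class:`~ddplex.quantify.AssayLayout`) to expected copies per reaction.
    ``rain_fraction`` is the proportion of positive droplets rendered at
    intermediate amplitude.
    """

    copies_per_reaction: Mapping[str, float]
    n_droplets: int = 15000
    droplet_volume_nL: float = 0.85
    reaction_volume_uL: float = 20.0
    channel1: ChannelModel = field(default_factory=ChannelModel)
    channel2: ChannelModel = field(default_factory=ChannelModel)
    rain_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_droplets < 1:
            raise ValueError("n_droplets must be at least 1")
        if self.droplet_volume_nL <= 0:
            raise ValueError("droplet_volume_nL must be positive")
        if self.reaction_volume_uL <= 0:
            raise ValueError("reaction_volume_uL must be positive")
        if not 0 <= self.rain_fraction < 1:
            raise ValueError("rain_fraction must lie in [0, 1)")
        for name, c in dict(self.copies_per_reaction).items():
            if c < 0:
                raise ValueError(f"copies_per_reaction[{name!r}] must be >= 0")
        object.__setattr__(
            self, "copies_per_reaction", dict(self.copies_per_reaction)
        )

    def channel(self, index: int) -> ChannelModel:
        if index == 1:
            return self.channel1
        if index == 2:
            return self.channel2
        raise ValueError(f"channel must be 1 or 2, got {index}")


@dataclass(frozen=True)
class GroundTruth:
    """Per-droplet truth for a simulated well.

    ``copies``: (n_droplets, n_targets) integer copy counts in layout order;
    ``band_ch1``/``band_ch2``: true band index per droplet derived from
    which same-channel targets have at least one copy; ``is_rain``: droplets
    rendered by the rain law; ``target_names``: layout order of the columns.
    """

    copies: np.ndarray
    band_ch1: np.ndarray
    band_ch2: np.ndarray
    is_rain: np.ndarray
    target_names: tuple[str, ...]

    def positive_droplets(self, target_name: str) -> int:
        """Droplets carrying at least one copy of the named target."""
        col = self.target_names.index(target_name)
        return int((self.copies[:, col] > 0).sum())

    def realized_copies_per_reaction(
        self, target_name: str, config: SimulationConfig
    ) -> float:
        """Copies per reaction implied by the copies actually in the droplets."""
        col = self.target_names.index(target_name)
        lam = float(self.copies[:, col].mean())
        return (
            lam / (config.droplet_volume_nL / 1000.0) * config.reaction_volume_uL
        )


def lambda_from_copies(copies_per_reaction: float, config: SimulationConfig) -> float:
    """Mean copies per droplet implied by a copies-per-reaction value."""
    if copies_per_reaction < 0:
        raise ValueError("copies_per_reaction must be >= 0")
    return (
        copies_per_reaction
        / config.reaction_volume_uL
        * (config.droplet_volume_nL / 1000.0)
    )


def _true_band(present: Sequence[np.ndarray], levels: Sequence[str]) -> np.ndarray:
    """Band index from presence flags of the (up to 2) same-channel targets."""
    n = present[0].size if present else 0
    band = np.zeros(n, dtype=int)
    if len(present) == 1:
        return present[0].astype(int)
    for flags, level in zip(present, levels):
        band += flags.astype(int) * (1 if level == "low" else 2)
    return band


def theoretical_grid(config: SimulationConfig, layout: AssayLayout) -> SeparationGrid:
    """Separation lines at midpoints between the configured true cluster means.

    This is the grid a scientist would set manually from a positive control
    under the generator's amplitude model; useful when automatic placement
    is not identifiable (e.g. an absent target leaves too few clusters).
    """
    lines: dict[int, tuple[float, ...]] = {}
    for ch in (1, 2):
        model = config.channel(ch)
        targets = layout.targets_on_channel(ch)
        b = model.baseline_mean
        if len(targets) == 0:
            lines[ch] = ()
        elif len(targets) == 1:
            inc = model.increment(targets[0].level)
            lines[ch] = (b + inc / 2.0,)
        else:
            low, high = model.low_increment, model.high_increment
            lines[ch] = (
                b + low / 2.0,
                b + (low + high) / 2.0,
                b + high + low / 2.0,
            )
    return SeparationGrid(lines[1], lines[2], provenance="manual")


def simulate_well(
    config: SimulationConfig, layout: AssayLayout
) -> tuple[DropletSet, GroundTruth]:
    """Simulate one well: droplet amplitudes plus per-droplet ground truth.

    Identical configs (including seed) give bit-identical output.
    """
    missing = [t.name for t in layout.targets if t.name not in config.copies_per_reaction]
    if missing:
        raise ValueError(f"config lacks copies_per_reaction for targets {missing}")
    rng = np.random.default_rng(config.seed)
    n = config.n_droplets
    names = tuple(t.name for t in layout.targets)

    copies = np.empty((n, len(names)), dtype=int)
    for k, t in enumerate(layout.targets):
        lam = lambda_from_copies(config.copies_per_reaction[t.name], config)
        copies[:, k] = rng.poisson(lam, size=n)
    present = copies > 0

    any_positive = present.any(axis=1)
    is_rain = np.zeros(n, dtype=bool)
    if config.rain_fraction > 0:
        is_rain = any_positive & (rng.random(n) < config.rain_fraction)

    amplitudes: dict[int, np.ndarray] = {}
    bands: dict[int, np.ndarray] = {}
    for ch in (1, 2):
        model = config.channel(ch)
        targets = layout.targets_on_channel(ch)
        idx = [names.index(t.name) for t in targets]
        flags = [present[:, i] for i in idx]
        levels = [t.level for t in targets]
        band = _true_band(flags, levels) if targets else np.zeros(n, dtype=int)
        cluster_mean = np.full(n, model.baseline_mean)
        for f, level in zip(flags, levels):
            cluster_mean = cluster_mean + f * model.increment(level)
        positive_here = band > 0
        sd = np.where(positive_here, model.cluster_sd, model.baseline_sd)
        amp = cluster_mean + rng.normal(0.0, 1.0, size=n) * sd
        rain_here = is_rain & positive_here
        if rain_here.any():
            u = rng.random(int(rain_here.sum()))
            amp[rain_here] = model.baseline_mean + u * (
                cluster_mean[rain_here] - model.baseline_mean
            )
        amplitudes[ch] = amp
        bands[ch] = band

    droplets = DropletSet(well_id=f"sim-{config.seed}", ch1=amplitudes[1], ch2=amplitudes[2])
    truth = GroundTruth(
        copies=copies,
        band_ch1=bands[1],
        band_ch2=bands[2],
        is_rain=is_rain,
        target_names=names,
    )
    return droplets, truth


@dataclass(frozen=True)
class DilutionLevel:
    """Replicate measurements of one dilution level of one target."""

    level_id: str
    assigned_copies: float
    replicate_values: tuple[float, ...]
    replicate_positive_droplets: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.replicate_values) == 0:
            raise ValueError("a dilution level needs at least one replicate")
        if len(self.replicate_values) != len(self.replicate_positive_droplets):
            raise ValueError("replicate value and droplet-count lists must be parallel")
        if self.assigned_copies < 0:
            raise ValueError("assigned_copies must be >= 0")


def _child_seed(base_seed: int, level: int, rep: int) -> int:
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(level, rep))
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_dilution_series(
    base_config: SimulationConfig,
    layout: AssayLayout,
    dilution_factors: Sequence[float],
    replicates_per_level: int,
    *,
    scale_target: str | None = None,
    target: str | None = None,
    quant_config: QuantConfig | None = None,
    grid: SeparationGrid | None = None,
):
    """Simulate and quantify a dilution series.

    One well is simulated per (level, replicate); each well is classified
    (default: the config-derived :func:`theoretical_grid`, standing in for
    positive-control-derived manual lines) and quantified. With
    ``scale_target`` set, only that target is diluted while the others stay
    at their base concentrations, emulating asymmetric detection-limit
    designs.

    Returns a dict mapping target name to a list of
    :class:`DilutionLevel`, or a single list when ``target`` is given.
    """
    if replicates_per_level < 1:
        raise ValueError("replicates_per_level must be at least 1")
    factors = [float(f) for f in dilution_factors]
    if any(f <= 0 for f in factors):
        raise ValueError("dilution factors must be positive")
    quant_config = quant_config or QuantConfig(
        droplet_volume_nL=base_config.droplet_volume_nL,
        reaction_volume_uL=base_config.reaction_volume_uL,
    )
    names = [t.name for t in layout.targets]
    series: dict[str, list[DilutionLevel]] = {name: [] for name in names}

    for li, f in enumerate(factors):
        scaled = {
            name: (c * f if scale_target in (None, name) else c)
            for name, c in base_config.copies_per_reaction.items()
        }
        values: dict[str, list[float]] = {name: [] for name in names}
        droplet_counts: dict[str, list[int]] = {name: [] for name in names}
        for rep in range(replicates_per_level):
            cfg = replace(
                base_config,
                copies_per_reaction=scaled,
                seed=_child_seed(base_config.seed, li, rep),
            )
            droplets, _ = simulate_well(cfg, layout)
            g = grid or theoretical_grid(cfg, layout)
            results = quantify_multiplex(classify(droplets, g), layout, quant_config)
            for r in results:
                values[r.target_name].append(r.copies_per_reaction)
                droplet_counts[r.target_name].append(r.positives)
        for name in names:
            assigned = scaled[name]
            series[name].append(
                DilutionLevel(
                    level_id=f"L{li + 1}",
                    assigned_copies=assigned,
                    replicate_values=tuple(values[name]),
                    replicate_positive_droplets=tuple(droplet_counts[name]),
                )
            )
    if target is not None:
        if target not in series:
            raise KeyError(f"no target named {target!r} in layout")
        return series[target]
    return series


def write_ground_truth(truth: GroundTruth, stream: IO[str]) -> None:
    """Write per-droplet ground truth as a tab-delimited table."""
    header = (
        [f"copies_{n}" for n in truth.target_names]
        + ["band_ch1", "band_ch2", "is_rain"]
    )
    stream.write("\t".join(header) + "\n")
    for i in range(truth.copies.shape[0]):
        row = (
            [str(int(c)) for c in truth.copies[i]]
            + [str(int(truth.band_ch1[i])), str(int(truth.band_ch2[i]))]
            + ["1" if truth.is_rain[i] else "0"]
        )
        stream.write("\t".join(row) + "\n")


def write_amplitude_csv(droplets: DropletSet, stream: IO[str]) -> None:
    """Write a droplet set in the comma-separated amplitude export dialect."""
    stream.write("Ch1 Amplitude,Ch2 Amplitude\n")
    for a, b in zip(droplets.ch1, droplets.ch2):
        stream.write(f"{a:.3f},{b:.3f}\n")
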