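"""Model/Results interface over the classification + quantification pipeline.

:class:`MultiplexModel` holds the data (one well's droplet amplitudes) and
the design (assay layout, quantification settings); ``fit()`` places the
separation grid (automatically, or from supplied lines), classifies every
droplet and returns a :class:`MultiplexResults` carrying the per-target
Poisson estimates, their confidence intervals, the cluster table and a
``summary()``.

Example
-------
>>> from ddplex import MultiplexModel, example_tetraplex
>>> from ddplex.simulate import SimulationConfig, simulate_well
>>> layout = example_tetraplex()
>>> cfg = SimulationConfig(
...     copies_per_reaction={t.name: 500.0 for t in layout.targets}, seed=7)
>>> droplets, _ = simulate_well(cfg, layout)
>>> res = MultiplexModel(droplets, layout).fit()
>>> print(res.summary())  # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO

import numpy as np
import pandas as pd

from .clustering import ClusterGrid, SeparationGrid, classify, propose_grid
from .io import DropletSet, read_amplitude_export, write_results_table
from .quantify import AssayLayout, QuantConfig, TargetResult, quantify_multiplex

__all__ = ["MultiplexModel", "MultiplexResults"]


class MultiplexModel:
    """Absolute multiplex quantification model for one well.

    Parameters
    ----------
    droplets
        The well's two-channel droplet amplitudes.
    layout
        Target-to-(channel, level) binding.
    config
        Quantification settings (volumes, CI level and method, detection
        threshold); defaults to :class:`~ddplex.quantify.QuantConfig`.
    """

    def __init__(
        self,
        droplets: DropletSet,
        layout: AssayLayout,
        config: QuantConfig | None = None,
    ) -> None:
        self.droplets = droplets
        self.layout = layout
        self.config = config or QuantConfig()

    @classmethod
    def from_csv(
        cls,
        path_or_stream,
        layout: AssayLayout,
        *,
        well_id: str = "well",
        config: QuantConfig | None = None,
        **read_kwargs,
    ) -> "MultiplexModel":
        """Build a model straight from a raw amplitude export."""
        droplets = read_amplitude_export(path_or_stream, well_id, **read_kwargs)
        return cls(droplets, layout, config)

    def fit(self, grid: SeparationGrid | None = None, **propose_kwargs) -> "MultiplexResults":
        """Place the separation grid, classify and quantify.

        With ``grid=None`` the lines are proposed automatically from the
        amplitude densities (extra keyword arguments reach
        :func:`~ddplex.clustering.propose_lines_1d`); passing a grid uses it
        as-is, e.g. manual lines from a positive control.
        """
        if grid is None:
            grid = propose_grid(self.droplets, self.layout, **propose_kwargs)
        cluster_grid = classify(self.droplets, grid)
        results = quantify_multiplex(
            cluster_grid, self.layout, self.config, self.droplets.well_id
        )
        return MultiplexResults(self, grid, cluster_grid, tuple(results))


@dataclass(frozen=True)
class MultiplexResults:
    """Fitted quantification results for one well."""

    model: MultiplexModel
    grid: SeparationGrid
    cluster_grid: ClusterGrid
    targets: tuple[TargetResult, ...]

    def target(self, name: str) -> TargetResult:
        for r in self.targets:
            if r.target_name == name:
                return r
        raise KeyError(f"no target named {name!r}")

    def to_frame(self) -> pd.DataFrame:
        """Per-target results as a DataFrame (layout order)."""
        return pd.DataFrame(
            {
                "well": [r.well_id for r in self.targets],
                "target": [r.target_name for r in self.targets],
                "positives": [r.positives for r in self.targets],
                "total": [r.total for r in self.targets],
                "p_hat": [r.p_hat for r in self.targets],
                "lambda": [r.lambda_ for r in self.targets],
                "copies_per_uL": [r.copies_per_uL for r in self.targets],
                "copies_per_reaction": [r.copies_per_reaction for r in self.targets],
                "ci_low": [r.ci_low for r in self.targets],
                "ci_high": [r.ci_high for r in self.targets],
                "detected": [r.detected for r in self.targets],
                "saturated": [r.saturated for r in self.targets],
            }
        )

    def write_table(self, stream: IO[str], *, digits: int = 4) -> None:
        """Export the results as a tab-delimited table."""
        write_results_table(self.targets, stream, digits=digits)

    def summary(self) -> str:
        """Human-readable summary: grid, cluster occupancy and estimates."""
        m = self.model
        lines = [
            f"Multiplex ddPCR quantification — well {m.droplets.well_id!r}, "
            f"assay {m.layout.assay_name!r}",
            f"accepted droplets: {m.droplets.n_accepted}",
            f"separation lines ({self.grid.provenance}): "
            f"ch1 {[round(x, 1) for x in self.grid.ch1_lines]}, "
            f"ch2 {[round(x, 1) for x in self.grid.ch2_lines]}",
            f"confidence level: {m.config.ci_level:.0%} ({m.config.ci_method})",
            "",
            f"{'target':<12}{'positives':>10}{'lambda':>10}{'copies/rxn':>12}"
            f"{'ci_low':>10}{'ci_high':>10}{'detected':>10}",
        ]
        for r in self.targets:
            lines.append(
                f"{r.target_name:<12}{r.positives:>10d}{r.lambda_:>10.4g}"
                f"{r.copies_per_reaction:>12.6g}{r.ci_low:>10.5g}{r.ci_high:>10.5g}"
                f"{('yes' if r.detected else 'no'):>10}"
            )
        lines.append("")
        lines.append("cluster counts (rows: ch1 band, cols: ch2 band):")
        for row in np.asarray(self.cluster_grid.counts):
            lines.append("  " + "  ".join(f"{int(c):>7d}" for c in row))
        return "\n".join(lines)

    def plot(self, ax=None, max_points: int = 20000):
        """2-D amplitude scatter with the separation grid overlaid."""
        import matplotlib

        if ax is None:
            matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 6))
        d = self.model.droplets
        n = d.n_accepted
        step = max(1, n // max_points)
        ax.scatter(d.ch2[::step], d.ch1[::step], s=2, alpha=0.4, linewidths=0)
        for y in self.grid.ch1_lines:
            ax.axhline(y, color="crimson", lw=0.8)
        for x in self.grid.ch2_lines:
            ax.axvline(x, color="crimson", lw=0.8)
        ax.set_xlabel("channel 2 amplitude")
        ax.set_ylabel("channel 1 amplitude")
        ax.set_title(f"well {d.well_id!r} ({self.grid.provenance} lines)")
        return ax
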