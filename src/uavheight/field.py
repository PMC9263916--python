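"""Field trial geometry: plots, rows, plants, measurement blocks.

The layout mirrors a maize variety trial: ``n_plots`` rectangular plots tiled
on a grid inside an analysis region, each plot holding ``rows_per_plot``
planting rows (rows run along the y axis, spaced ``row_spacing`` apart in x)
of ``plants_per_row`` plants at ``plant_spacing``. Ground-truth height is
taken on the middle rows of each plot ("measured rows"): five consecutive
plants per row are measured with a ruler and averaged into one sample.

Each row is additionally divided into ``blocks_per_row`` consecutive blocks
of plants; the measured five plants sit centered in the middle block. The
measured rows are split into three spatially contiguous groups (thirds of the
plot grid in planting order), which later serve as the hold-out groups of the
cross-flight validation.

All coordinates are local planar meters with the origin at the south-west
corner of the analysis region; no geodetic CRS is attached.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import LayoutError

__all__ = ["FieldLayout", "MeasuredRow", "make_field_layout", "planting_density"]

N_GROUPS = 3


@dataclass(frozen=True)
class MeasuredRow:
    """One ground-truth sample unit: a measured row within a plot."""

    row_id: str
    plot: int
    row_index: int  # position of the row within its plot
    group: int  # spatial group in {1, 2, 3}
    x_center: float  # row centerline (m)
    y_start: float  # southern end of the row (first plant - half spacing)


@dataclass(frozen=True)
class FieldLayout:
    n_plots: int
    rows_per_plot: int = 4
    plants_per_row: int = 18
    row_spacing: float = 0.75
    plant_spacing: float = 0.18
    blocks_per_row: int = 3
    measured_row_indices: tuple[int, ...] = (1, 2)
    region_width: float = 35.5
    region_length: float = 54.0
    n_plot_cols: int = 7
    plot_gap_x: float = 0.5
    plot_gap_y: float = 0.5
    measured_block: int = 1
    n_measured_plants: int = 5

    # ---- derived geometry -------------------------------------------------

    @property
    def plot_width(self) -> float:
        return self.rows_per_plot * self.row_spacing

    @property
    def plot_length(self) -> float:
        return self.plants_per_row * self.plant_spacing

    @property
    def n_plot_rows(self) -> int:
        return math.ceil(self.n_plots / self.n_plot_cols)

    @property
    def region(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the analysis region."""
        return (0.0, 0.0, self.region_width, self.region_length)

    @property
    def n_measured_rows(self) -> int:
        return self.n_plots * len(self.measured_row_indices)

    def plot_origin(self, plot: int) -> tuple[float, float]:
        """South-west corner of a plot, plots numbered row-major from SW."""
        col, row = plot % self.n_plot_cols, plot // self.n_plot_cols
        total_w = self.n_plot_cols * self.plot_width + (self.n_plot_cols - 1) * self.plot_gap_x
        total_l = self.n_plot_rows * self.plot_length + (self.n_plot_rows - 1) * self.plot_gap_y
        x0 = (self.region_width - total_w) / 2.0
        y0 = (self.region_length - total_l) / 2.0
        return (
            x0 + col * (self.plot_width + self.plot_gap_x),
            y0 + row * (self.plot_length + self.plot_gap_y),
        )

    def row_x_center(self, plot: int, row_index: int) -> float:
        return self.plot_origin(plot)[0] + (row_index + 0.5) * self.row_spacing

    def plant_y_positions(self, plot: int) -> np.ndarray:
        y0 = self.plot_origin(plot)[1]
        return y0 + (np.arange(self.plants_per_row) + 0.5) * self.plant_spacing

    def block_plant_indices(self) -> list[np.ndarray]:
        """Plant indices of each consecutive block along a row."""
        return list(np.array_split(np.arange(self.plants_per_row), self.blocks_per_row))

    def measured_plant_indices(self) -> np.ndarray:
        """Indices of the measured plants, centered within the measured block."""
        block = self.block_plant_indices()[self.measured_block]
        if len(block) < self.n_measured_plants:
            raise LayoutError(
                f"measured block holds {len(block)} plants < "
                f"{self.n_measured_plants} to be measured"
            )
        start = (len(block) - self.n_measured_plants) // 2
        return block[start : start + self.n_measured_plants]

    def measured_rows(self) -> list[MeasuredRow]:
        """All measured rows in planting order, with spatial group labels."""
        rows = []
        for plot in range(self.n_plots):
            x0, y0 = self.plot_origin(plot)
            for r in self.measured_row_indices:
                rows.append((plot, r, self.row_x_center(plot, r), y0))
        thirds = np.array_split(np.arange(len(rows)), N_GROUPS)
        group_of = np.empty(len(rows), dtype=int)
        for g, idx in enumerate(thirds, start=1):
            group_of[idx] = g
        return [
            MeasuredRow(
                row_id=f"P{plot:03d}R{r}",
                plot=plot,
                row_index=r,
                group=int(group_of[k]),
                x_center=xc,
                y_start=y0,
            )
            for k, (plot, r, xc, y0) in enumerate(rows)
        ]

    def all_plant_positions(self) -> np.ndarray:
        """(n_plants_total, 2) x/y coordinates of every plant in the field."""
        pts = []
        for plot in range(self.n_plots):
            ys = self.plant_y_positions(plot)
            for r in range(self.rows_per_plot):
                x = self.row_x_center(plot, r)
                pts.append(np.column_stack([np.full_like(ys, x), ys]))
        return np.concatenate(pts, axis=0)


def make_field_layout(**kwargs) -> FieldLayout:
    """Build and validate a :class:`FieldLayout`.

    Raises :class:`LayoutError` if spacings/counts are non-positive, measured
    row indices fall outside the plot, or the plot grid does not fit inside
    the analysis region.
    """
    layout = FieldLayout(**kwargs)
    if min(layout.row_spacing, layout.plant_spacing) <= 0:
        raise LayoutError("row and plant spacing must be positive")
    if min(
        layout.n_plots,
        layout.rows_per_plot,
        layout.plants_per_row,
        layout.blocks_per_row,
        layout.n_plot_cols,
    ) <= 0:
        raise LayoutError("counts must be positive")
    if not layout.measured_row_indices:
        raise LayoutError("at least one measured row index is required")
    if not all(0 <= r < layout.rows_per_plot for r in layout.measured_row_indices):
        raise LayoutError("measured_row_indices must lie within [0, rows_per_plot)")
    if not (0 <= layout.measured_block < layout.blocks_per_row):
        raise LayoutError("measured_block must lie within [0, blocks_per_row)")
    total_w = layout.n_plot_cols * layout.plot_width + (layout.n_plot_cols - 1) * layout.plot_gap_x
    total_l = (
        layout.n_plot_rows * layout.plot_length + (layout.n_plot_rows - 1) * layout.plot_gap_y
    )
    if total_w > layout.region_width + 1e-9 or total_l > layout.region_length + 1e-9:
        raise LayoutError(
            f"plot grid {total_w:.2f} x {total_l:.2f} m exceeds analysis region "
            f"{layout.region_width} x {layout.region_length} m"
        )
    layout.measured_plant_indices()  # validates block capacity
    return layout


def planting_density(layout: FieldLayout) -> float:
    """Plants per square meter, 1 / (row_spacing * plant_spacing)."""
    if layout.row_spacing <= 0 or layout.plant_spacing <= 0:
        raise LayoutError("spacings must be positive for a planting density")
    return 1.0 / (layout.row_spacing * layout.plant_spacing)
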