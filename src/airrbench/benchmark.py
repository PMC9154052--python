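"""Benchmark plan enumeration, scaled grid execution, and boundary maps.

The full benchmark plan is a set of rows, each varying one property of the
training setup (sample size, repertoire size, class balance, motif size,
...) across a list of values, crossed with a list of witness rates and
replicated on independent datasets (default 3).  ``enumerate_plan`` does
the exact dataset/repertoire/sequence bookkeeping without generating any
data; ``run_benchmark`` executes rows end-to-end at a configurable scale
factor suitable for desk-scale runs; ``discretize_boundary`` thresholds a
performance grid (mean balanced accuracy ≥ 0.7 AND sd ≤ 0.1 by default)
into an adequate/inadequate boundary map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .models import (
    ExperimentCell,
    PerformancePoint,
    TrainingConfig,
    replicate_experiment,
)
from .repertoires import _spawn_seeds
from .signals import witness_count

__all__ = [
    "DEFAULT_WITNESS_RATES",
    "PlanRow",
    "BenchmarkPlan",
    "PlanStats",
    "PerformanceGrid",
    "default_plan",
    "enumerate_plan",
    "run_benchmark",
    "discretize_boundary",
]

#: Witness rates (percent of sequences per positive repertoire) used across
#: the benchmark grid.
DEFAULT_WITNESS_RATES: tuple[float, ...] = (
    0.001,
    0.002,
    0.005,
    0.01,
    0.05,
    0.1,
    0.2,
)

DEFAULT_N_EXAMPLES = 200
DEFAULT_REPERTOIRE_SIZE = 100_000


@dataclass(frozen=True)
class PlanRow:
    """One benchmark-plan row: a property varied across values × rates.

    ``n_dataset_values`` may differ from ``len(values)`` when a row reuses
    datasets across its property values (e.g. the model feature-size row
    trains several models on the same datasets) or reuses data generated by
    other rows entirely (zero-dataset rows such as the distributional-shift
    row).  ``examples_per_value``/``repertoire_size_per_value`` override
    the defaults per property value when the varied property is itself a
    dataset size.
    """

    name: str
    property_name: str
    values: tuple = ()
    witness_rates: tuple[float, ...] = DEFAULT_WITNESS_RATES
    n_replications: int = 3
    n_dataset_values: int | None = None  # defaults to len(values)
    n_examples: int = DEFAULT_N_EXAMPLES
    repertoire_size: int = DEFAULT_REPERTOIRE_SIZE
    examples_per_value: tuple[int, ...] | None = None
    repertoire_size_per_value: tuple[int, ...] | None = None
    cell_kind: str = "unsupported"  # how run_benchmark builds cells

    @property
    def dataset_values(self) -> int:
        return len(self.values) if self.n_dataset_values is None else self.n_dataset_values

    @property
    def n_datasets(self) -> int:
        return self.dataset_values * len(self.witness_rates) * self.n_replications

    def _examples(self, value_index: int) -> int:
        if self.examples_per_value is not None:
            return self.examples_per_value[value_index]
        return self.n_examples

    def _repertoire_size(self, value_index: int) -> int:
        if self.repertoire_size_per_value is not None:
            return self.repertoire_size_per_value[value_index]
        return self.repertoire_size

    @property
    def n_repertoires(self) -> int:
        per_rate_rep = sum(self._examples(i) for i in range(self.dataset_values))
        return per_rate_rep * len(self.witness_rates) * self.n_replications

    @property
    def n_sequences(self) -> int:
        per_rate_rep = sum(
            self._examples(i) * self._repertoire_size(i)
            for i in range(self.dataset_values)
        )
        return per_rate_rep * len(self.witness_rates) * self.n_replications


@dataclass(frozen=True)
class BenchmarkPlan:
    rows: tuple[PlanRow, ...]

    def row(self, name: str) -> PlanRow:
        for r in self.rows:
            if r.name == name:
                return r
        raise KeyError(name)


@dataclass(frozen=True)
class PlanStats:
    """Exact bookkeeping of a plan: per-row and total counts."""

    per_row: pd.DataFrame  # columns: name, n_datasets, n_repertoires, n_sequences
    total_datasets: int
    total_repertoires: int
    total_sequences: int


def default_plan() -> BenchmarkPlan:
    """The full benchmark plan (all rows, unscaled)."""
    single_rate = (0.01,)
    noise_row_rate = (0.01,)  # positive-class witness rate for the noise row
    rows = (
        PlanRow(
            name="sample_size",
            property_name="n_examples",
            values=(50, 100, 200, 400, 800, 1600),
            examples_per_value=(50, 100, 200, 400, 800, 1600),
            cell_kind="sample_size",
        ),
        PlanRow(
            name="repertoire_size",
            property_name="repertoire_size",
            values=(12_000, 25_000, 50_000, 100_000, 200_000),
            repertoire_size_per_value=(12_000, 25_000, 50_000, 100_000, 200_000),
            cell_kind="repertoire_size",
        ),
        PlanRow(
            name="motifs_vs_repertoire_size",
            property_name="(n_motifs, repertoire_size)",
            values=(
                (1, 33_000),
                (2, 66_000),
                (4, 133_000),
                (8, 266_000),
                (16, 533_000),
                (32, 1_066_000),
                (64, 2_133_000),
            ),
            repertoire_size_per_value=(
                33_000,
                66_000,
                133_000,
                266_000,
                533_000,
                1_066_000,
                2_133_000,
            ),
            cell_kind="motifs_vs_repertoire_size",
        ),
        PlanRow(
            name="motif_size_ungapped",
            property_name="motif_size",
            values=(2, 3, 4, 5),
            cell_kind="motif_size",
        ),
        PlanRow(
            name="motif_size_gapped",
            property_name="motif_size",
            values=(3, 4, 5),
            cell_kind="motif_size_gapped",
        ),
        PlanRow(
            name="model_feature_size",
            property_name="encoding_k",
            values=(2, 3, 4, 5),
            n_dataset_values=1,  # the same 4-mer-signal datasets serve all k
            cell_kind="model_feature_size",
        ),
        PlanRow(
            name="negative_class_noise",
            property_name="noise_rate",
            values=(0.001, 0.003, 0.005, 0.007, 0.009, 0.01),
            witness_rates=noise_row_rate,
            cell_kind="noise",
        ),
        PlanRow(
            name="regularization_strength",
            property_name="n_motifs",
            values=(1, 64),
            cell_kind="unsupported",  # per-C evaluation, not a nested-CV grid
        ),
        PlanRow(
            name="test_witness_rate",
            property_name="test_witness_rate",
            values=DEFAULT_WITNESS_RATES,
            n_dataset_values=0,  # reuses training data; see evaluate_transfer
            cell_kind="unsupported",
        ),
        PlanRow(
            name="class_balance",
            property_name="positive_fraction",
            values=(0.05, 0.10, 0.20, 0.40, 0.60, 0.80, 0.90, 0.95),
            cell_kind="class_balance",
        ),
        PlanRow(
            name="dataset_source",
            property_name="source_kind",
            values=("random", "meta_pool", "subsampled"),
            cell_kind="unsupported",
        ),
        PlanRow(
            name="ml_model",
            property_name="model_kind",
            values=("logreg_l1", "svc_l1", "svc_l2", "random_forest"),
            n_dataset_values=0,  # reuses previously generated datasets
            cell_kind="unsupported",
        ),
        PlanRow(
            name="svc_l1_regularization",
            property_name="C",
            values=(0.01, 0.05, 0.1, 1, 5, 10, 50, 100, 1_000, 100_000, 10_000_000),
            n_dataset_values=0,
            cell_kind="unsupported",
        ),
        PlanRow(
            name="rf_estimators",
            property_name="n_estimators",
            values=(1, 2, 5, 10, 25, 50, 100, 200, 500, 1_000, 2_000, 5_000),
            n_dataset_values=0,
            cell_kind="unsupported",
        ),
        PlanRow(
            name="n_motifs_feature_selection",
            property_name="n_motifs",
            values=(4, 16, 64),
            cell_kind="n_motifs",
        ),
        PlanRow(
            name="minority_examples_vs_nonzero_coefficients",
            property_name="(n_minority, s)",
            values=tuple(
                (n, s) for s in (2, 4, 8, 16) for n in (20, 40, 80, 160, 320)
            ),
            # dataset size = 2.5 × minority count: balanced classes, with the
            # minority count defined inside the 80% training split of the CV
            examples_per_value=tuple(
                int(2.5 * n) for s in (2, 4, 8, 16) for n in (20, 40, 80, 160, 320)
            ),
            witness_rates=single_rate,
            cell_kind="unsupported",
        ),
        PlanRow(
            name="minority_examples_vs_predictors",
            property_name="(n_minority, log_p)",
            values=tuple((n, lp) for lp in (6, 8, 10, 12) for n in (20, 40, 80, 160)),
            examples_per_value=tuple(
                int(2.5 * n) for lp in (6, 8, 10, 12) for n in (20, 40, 80, 160)
            ),
            witness_rates=single_rate,
            cell_kind="unsupported",
        ),
    )
    return BenchmarkPlan(rows=rows)


def enumerate_plan(plan: BenchmarkPlan) -> PlanStats:
    """Exact dataset/repertoire/sequence bookkeeping; generates nothing."""
    records = []
    for row in plan.rows:
        records.append(
            {
                "name": row.name,
                "n_datasets": row.n_datasets,
                "n_repertoires": row.n_repertoires,
                "n_sequences": row.n_sequences,
            }
        )
    per_row = pd.DataFrame(
        records, columns=["name", "n_datasets", "n_repertoires", "n_sequences"]
    )
    return PlanStats(
        per_row=per_row,
        total_datasets=int(per_row["n_datasets"].sum()) if len(per_row) else 0,
        total_repertoires=int(per_row["n_repertoires"].sum()) if len(per_row) else 0,
        total_sequences=int(per_row["n_sequences"].sum()) if len(per_row) else 0,
    )


@dataclass
class PerformanceGrid:
    """Performance points indexed by (property value, witness rate)."""

    points: dict[tuple, PerformancePoint] = field(default_factory=dict)
    scale: float = 1.0
    scale_mode: str = "proportional"

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for (value, rate), point in self.points.items():
            rows.append(
                {
                    "value": value,
                    "witness_rate": rate,
                    "mean_balanced_accuracy": point.mean_balanced_accuracy,
                    "sd_balanced_accuracy": point.sd_balanced_accuracy,
                    "n_replications": point.n_replications,
                }
            )
        return pd.DataFrame(rows)


def _build_cell(row: PlanRow, value, value_index: int, rate: float, scale: float,
                scale_mode: str) -> ExperimentCell:
    n_examples = max(1, round(row._examples(value_index) * scale))
    repertoire_size = max(1, round(row._repertoire_size(value_index) * scale))
    if scale_mode == "witness_count_preserving" and rate > 0:
        target_count = witness_count(rate, row._repertoire_size(value_index))
        rate = 100.0 * target_count / repertoire_size
    kwargs: dict = {
        "witness_rate": rate,
        "n_examples": n_examples,
        "repertoire_size": repertoire_size,
    }
    kind = row.cell_kind
    if kind in ("sample_size", "repertoire_size"):
        pass  # the varied property is already folded into the sizes above
    elif kind == "motif_size":
        kwargs["motif_size"] = value
    elif kind == "motif_size_gapped":
        kwargs["motif_size"] = value
        kwargs["gapped"] = True
    elif kind == "model_feature_size":
        kwargs["encoding_k"] = value
    elif kind == "noise":
        kwargs["noise_rate"] = value
    elif kind == "class_balance":
        kwargs["positive_fraction"] = value
    elif kind == "n_motifs":
        kwargs["n_motifs"] = value
    elif kind == "motifs_vs_repertoire_size":
        kwargs["n_motifs"] = value[0]
    else:
        raise ValueError(
            f"row {row.name!r} reuses data or varies the model itself and is "
            "not runnable as a fresh-dataset grid"
        )
    return ExperimentCell(**kwargs)


def run_benchmark(
    plan: BenchmarkPlan | PlanRow,
    master_seed: int = 0,
    scale: float = 1.0,
    scale_mode: str = "proportional",
    config: TrainingConfig | None = None,
    n_replications: int | None = None,
) -> PerformanceGrid:
    """Run every runnable (value, rate) cell of a plan end-to-end.

    ``scale`` in (0, 1] multiplies both the per-dataset example count and
    the repertoire size.  ``scale_mode='proportional'`` keeps witness rates
    fixed (faithful, but the absolute implant count shrinks with the
    repertoire); ``'witness_count_preserving'`` rescales the rate so the
    implant count per repertoire matches the unscaled design.  Feasibility
    (≥ 20 examples, ≥ 100 sequences per repertoire) is checked for every
    cell before any simulation.
    """
    if not 0 < scale <= 1:
        raise ValueError("scale must lie in (0, 1]")
    if scale_mode not in ("proportional", "witness_count_preserving"):
        raise ValueError(f"unknown scale mode {scale_mode!r}")
    rows = plan.rows if isinstance(plan, BenchmarkPlan) else (plan,)

    cells: list[tuple[PlanRow, object, ExperimentCell, int]] = []
    for row in rows:
        if row.cell_kind == "unsupported":
            continue
        reps = n_replications if n_replications is not None else row.n_replications
        # Every property value gets freshly simulated datasets here, even for
        # rows whose bookkeeping counts shared datasets; the enumeration stays
        # exact via enumerate_plan.
        for i, value in enumerate(row.values):
            for rate in row.witness_rates:
                cell = _build_cell(row, value, i, rate, scale, scale_mode)
                if cell.n_examples < 20 or cell.repertoire_size < 100:
                    raise ValueError(
                        f"scale {scale} yields an infeasible cell for row "
                        f"{row.name!r}: {cell.n_examples} examples × "
                        f"{cell.repertoire_size} sequences"
                    )
                cells.append((row, value, cell, reps))

    grid = PerformanceGrid(scale=scale, scale_mode=scale_mode)
    seeds = _spawn_seeds(master_seed, len(cells))
    for seed, (row, value, cell, reps) in zip(seeds, cells):
        point = replicate_experiment(
            cell, n_replications=reps, config=config, seed=seed
        )
        grid.points[(value, cell.witness_rate)] = point
    return grid


def discretize_boundary(
    grid: PerformanceGrid | pd.DataFrame,
    acc_threshold: float = 0.7,
    sd_threshold: float = 0.1,
) -> dict[tuple, bool]:
    """Mark each cell adequate iff mean ≥ acc_threshold AND sd ≤ sd_threshold."""
    if isinstance(grid, PerformanceGrid):
        items = [
            (key, p.mean_balanced_accuracy, p.sd_balanced_accuracy)
            for key, p in grid.points.items()
        ]
    else:
        items = [
            (
                (row.value, row.witness_rate),
                row.mean_balanced_accuracy,
                row.sd_balanced_accuracy,
            )
            for row in grid.itertuples()
        ]
    return {
        key: bool(mean >= acc_threshold and sd <= sd_threshold)
        for key, mean, sd in items
    }
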