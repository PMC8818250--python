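"""Synthetic colony screens with known ground truth.

The generative model mirrors the effects the analysis is built to correct:
colony sizes are lognormal around a baseline, each plate carries its own
multiplicative growth factor (incubation/nutrition differences), control
plates carry a peripheral edge gradient (border colonies face less
competition for nutrients; the gradient is condition-specific, which is
what makes spatial smoothing matter), a planted growth defect delta scales
an affected strain's experimental colonies by exp(-delta) so its true LGR
is exactly delta, and pinning failures zero control colonies so the
control-dead rule is exercised. Replicates of a strain are pinned as
contiguous 2x2 (4-replicate) or 4x4 (16-replicate) quadrant blocks.

All randomness flows from one seeded NumPy generator with a fixed draw
order (strain-layout permutation, plate multipliers per condition, then per
plate: noise field and failure mask), so a given seed reproduces the screen
byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .plate_io import CONTROL_ID, ArrayFormat, ColonyGrid, KeyMap

_BLOCK_EDGE = {1: 1, 4: 2, 16: 4}


@dataclass
class SimulationConfig:
    """Study conditions for a simulated screen.

    Defaults describe a full-scale screen: 1536-density plates, 17 plates,
    4 replicates per strain (~6.5k strains), lognormal size noise of
    sigma 0.1 on the log scale, plate effects of sigma 0.1, a 30% edge
    overgrowth on control plates, a 1% pinning-failure rate and two
    independent controls.
    """

    format: ArrayFormat = field(default_factory=lambda: ArrayFormat.from_total(1536))
    n_plates: int = 17
    replicates: int = 4
    baseline_size: float = 500.0
    noise_sigma: float = 0.1
    plate_effect_sigma: float = 0.1
    edge_amplitude: float = 0.3
    planted_effects: Mapping[str, float] = field(default_factory=dict)
    pinning_failure_rate: float = 0.01
    n_controls: int = 2
    control_positions: Sequence[tuple[int, int, int]] | None = None
    control1_artifacts: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates not in _BLOCK_EDGE:
            raise ValueError("replicates must be 1, 4 or 16")
        if self.n_controls not in (1, 2):
            raise ValueError("n_controls must be 1 or 2")
        if not 0 <= self.pinning_failure_rate < 1:
            raise ValueError("pinning_failure_rate must lie in [0, 1)")
        for sid, delta in self.planted_effects.items():
            if not np.isfinite(delta):
                raise ValueError(f"planted effect for {sid!r} is not finite")


@dataclass
class GroundTruth:
    """True per-strain LGRs and the positions where pinning failed."""

    effects: dict[str, float]
    failed_positions: set[tuple[str, int, int, int]]  # (condition, plate, row, col)

    def true_lgr(self, strain_id: str) -> float:
        return self.effects.get(strain_id, 0.0)


@dataclass
class SimulatedScreen:
    experiment: list[ColonyGrid]
    controls: list[list[ColonyGrid]]
    key: KeyMap
    truth: GroundTruth
    config: SimulationConfig


def _layout(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[KeyMap, dict[str, float]]:
    """Assign strain IDs to quadrant blocks, scattering planted strains.

    Planted strains are placed at seeded-random block positions: clustering
    them, or spacing them at a regular stride, lines affected colonies up in
    shared rows or columns, where a median-based spatial correction would
    mistake the planted biology for a plate artifact.
    """
    fmt = config.format
    b = _BLOCK_EDGE[config.replicates]
    blocks_per_plate = (fmt.rows // b) * (fmt.columns // b)
    capacity = blocks_per_plate * config.n_plates
    planted = list(config.planted_effects)
    if len(planted) > capacity:
        raise ValueError(
            f"{len(planted)} planted strains exceed the key capacity of "
            f"{capacity} strain blocks"
        )
    names: list[str | None] = [None] * capacity
    if planted:
        slots = rng.permutation(capacity)[: len(planted)]
        for sid, slot in zip(planted, slots):
            names[slot] = sid
    k = 1
    for i in range(capacity):
        if names[i] is None:
            names[i] = f"S{k:05d}"
            k += 1
    entries: dict[tuple[int, int, int], str] = {}
    idx = 0
    for plate in range(1, config.n_plates + 1):
        for br in range(fmt.rows // b):
            for bc in range(fmt.columns // b):
                sid = names[idx]
                idx += 1
                for dr in range(b):
                    for dc in range(b):
                        entries[(plate, br * b + dr + 1, bc * b + dc + 1)] = sid
    if config.control_positions:
        for plate, row, col in config.control_positions:
            entries[(plate, row, col)] = CONTROL_ID
    effects = {sid: 0.0 for sid in names}
    effects.update({sid: float(d) for sid, d in config.planted_effects.items()})
    effects[CONTROL_ID] = 0.0
    return KeyMap(entries=entries), effects


def _edge_matrix(fmt: ArrayFormat, amplitude: float) -> np.ndarray:
    edge = np.ones((fmt.rows, fmt.columns))
    if amplitude:
        edge[0, :] = edge[-1, :] = 1.0 + amplitude
        edge[:, 0] = edge[:, -1] = 1.0 + amplitude
    return edge


def simulate_screen(config: SimulationConfig) -> SimulatedScreen:
    """Generate experimental and control plate sets with known ground truth."""
    fmt = config.format
    rng = np.random.default_rng(config.seed)
    key, effects = _layout(config, rng)
    shape = (fmt.rows, fmt.columns)

    delta = np.zeros((config.n_plates, *shape))
    artifact = np.zeros((config.n_plates, *shape))
    for (plate, row, col), sid in key.entries.items():
        delta[plate - 1, row - 1, col - 1] = effects[sid]
        artifact[plate - 1, row - 1, col - 1] = config.control1_artifacts.get(sid, 0.0)

    edge = _edge_matrix(fmt, config.edge_amplitude)
    exp_mult = np.exp(rng.normal(0.0, config.plate_effect_sigma, config.n_plates))
    ctl_mult = [
        np.exp(rng.normal(0.0, config.plate_effect_sigma, config.n_plates))
        for _ in range(config.n_controls)
    ]

    experiment: list[ColonyGrid] = []
    controls: list[list[ColonyGrid]] = [[] for _ in range(config.n_controls)]
    failed: set[tuple[str, int, int, int]] = set()
    for p in range(config.n_plates):
        noise = np.exp(rng.normal(0.0, config.noise_sigma, shape))
        sizes = config.baseline_size * exp_mult[p] * np.exp(-delta[p]) * noise
        experiment.append(
            ColonyGrid(fmt, p + 1, "experiment", sizes)
        )
        for c in range(config.n_controls):
            noise = np.exp(rng.normal(0.0, config.noise_sigma, shape))
            sizes = config.baseline_size * ctl_mult[c][p] * edge * noise
            if c == 0:
                sizes = sizes * np.exp(artifact[p])
            if config.pinning_failure_rate > 0:
                fail = rng.random(shape) < config.pinning_failure_rate
                sizes = np.where(fail, 0.0, sizes)
                for r, col in zip(*np.nonzero(fail)):
                    failed.add((f"control{c + 1}", p + 1, int(r) + 1, int(col) + 1))
            controls[c].append(ColonyGrid(fmt, p + 1, f"control{c + 1}", sizes))

    truth = GroundTruth(effects=effects, failed_positions=failed)
    return SimulatedScreen(experiment, controls, key, truth, config)


# ---------------------------------------------------------------------------
# file emission


def _log_frame(grids: Sequence[ColonyGrid]) -> pd.DataFrame:
    parts = []
    for g in grids:
        parts.append(
            pd.DataFrame(
                {
                    "plate": g.plate,
                    "index": np.arange(g.format.total),
                    "size": g.sizes.ravel(),
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


def write_simulated_inputs(sim: SimulatedScreen, destination) -> dict[str, Path]:
    """Emit the simulated screen in every accepted input dialect.

    Writes one tab-delimited log file per condition, a combined generic
    Label/Plate/Row/Column/colonysize table, the key file, and a ground
    truth table (strain ID, true LGR, number of failed control positions).
    """
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    conditions = {"experiment": sim.experiment}
    for i, grids in enumerate(sim.controls, start=1):
        conditions[f"control{i}"] = grids

    generic_parts = []
    for label, grids in conditions.items():
        frame = _log_frame(grids)
        path = dest / f"{label}.log"
        frame.to_csv(path, sep="\t", index=False, float_format="%.17g", lineterminator="\n")
        paths[label] = path
        fmt = grids[0].format
        idx = frame["index"].to_numpy()
        generic_parts.append(
            pd.DataFrame(
                {
                    "Label": label,
                    "Plate": frame["plate"],
                    "Row": idx // fmt.columns + 1,
                    "Column": idx % fmt.columns + 1,
                    "colonysize": frame["size"],
                }
            )
        )
    generic = pd.concat(generic_parts, ignore_index=True)
    paths["generic"] = dest / "colonies_generic.csv"
    generic.to_csv(paths["generic"], index=False, float_format="%.17g", lineterminator="\n")

    key_rows = [
        {"Plate": p, "Row": r, "Column": c, "ID": sid}
        for (p, r, c), sid in sorted(sim.key.entries.items())
    ]
    paths["key"] = dest / "key.csv"
    pd.DataFrame(key_rows).to_csv(paths["key"], index=False, lineterminator="\n")

    n_failed: dict[str, int] = {}
    for condition, plate, row, col in sim.truth.failed_positions:
        sid = sim.key.id_at(plate, row, col)
        if sid is not None:
            n_failed[sid] = n_failed.get(sid, 0) + 1
    truth_rows = [
        {
            "ID": sid,
            "true_lgr": lgr,
            "n_failed_positions": n_failed.get(sid, 0),
        }
        for sid, lgr in sorted(sim.truth.effects.items())
    ]
    paths["ground_truth"] = dest / "ground_truth.csv"
    pd.DataFrame(truth_rows).to_csv(paths["ground_truth"], index=False, lineterminator="\n")
    return paths
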