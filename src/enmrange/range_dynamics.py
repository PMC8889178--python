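"""Suitability projection, consensus maps, and range-change statistics.

Fitted models (or an ensemble) are projected onto a scenario raster
stack to give per-pixel suitability.  A consensus binary map marks a
pixel suitable when more than half of the candidate models score it
above their own TSS-maximising cutoff.  Comparing the current and a
future binary map classifies each pixel as never occupied, always
occupied, lost, or gained, from which range change is computed under
two dispersal extremes:

* full dispersal — every gained pixel counts as colonised;
* no dispersal — a gained pixel counts only when its habitat patch in
  the *future* map (8-connected by default) also contains at least one
  always-occupied pixel, i.e. gains disconnected from currently
  occupied habitat (including those on a separate island) are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .geodata import EnvStack

NEVER, ALWAYS, LOST, GAINED = 0, 1, 2, 3
TRANSITION_LEGEND = {NEVER: "never", ALWAYS: "always", LOST: "lost", GAINED: "gained"}


class GridMismatchError(ValueError):
    pass


class SchemaError(ValueError):
    """Scenario stack lacks a variable the models were trained on."""


class EmptyRangeError(ValueError):
    """Percent change undefined: the current range has no pixels."""


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 8:
        return np.ones((3, 3), dtype=int)
    if connectivity == 4:
        return ndimage.generate_binary_structure(2, 1)
    raise ValueError("connectivity must be 4 or 8")


@dataclass
class BinaryMap:
    """0/1 habitat grid defined on the stack mask (NaN outside)."""

    grid: np.ndarray  # float grid: 0, 1, NaN on masked-out cells
    mask: np.ndarray
    note: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.grid.shape != self.mask.shape:
            raise GridMismatchError("binary grid and mask shapes differ")
        self.grid = np.where(self.mask, self.grid, np.nan)

    @property
    def habitat(self) -> np.ndarray:
        return np.nan_to_num(self.grid, nan=0.0).astype(bool) & self.mask

    @property
    def n_habitat(self) -> int:
        return int(self.habitat.sum())


@dataclass
class TransitionMap:
    classes: np.ndarray  # int codes on masked-in cells, -1 outside
    mask: np.ndarray

    def counts(self) -> dict[str, int]:
        c = {}
        for code, name in TRANSITION_LEGEND.items():
            c[name] = int(((self.classes == code) & self.mask).sum())
        # conservation: the four classes partition the masked-in pixels
        assert sum(c.values()) == int(self.mask.sum())
        return c


@dataclass
class RangeChangeStats:
    mode: str
    n_current: int
    n_lost: int
    n_gained: int
    n_gained_counted: int
    loss_pct: float
    gain_pct: float
    net_change_pct: float


def project_models(models: Sequence, scenario: EnvStack,
                   variables: Sequence[str] | None = None) -> list[np.ndarray]:
    """Predict per-pixel suitability for each model on a scenario stack.

    Static (categorical) layers are expected to be carried over unchanged
    in the scenario stack.  Raises :class:`SchemaError` when a training
    variable is missing.
    """
    if variables is None:
        variables = scenario.names
    missing = [v for v in variables if v not in scenario.layers]
    if missing:
        raise SchemaError(f"scenario stack missing variables: {missing}")
    rows, cols = np.nonzero(scenario.mask)
    X = scenario.design_matrix(rows, cols)[list(variables)]
    out = []
    for m in models:
        grid = np.full(scenario.shape, np.nan)
        grid[rows, cols] = m.predict(X)
        out.append(grid)
    return out


def project_ensemble(ensemble, scenario: EnvStack,
                     variables: Sequence[str] | None = None) -> np.ndarray:
    return project_models([ensemble], scenario, variables)[0]


def binarize_consensus(model_maps: Sequence[np.ndarray],
                       cutoffs: Sequence[float], mask: np.ndarray,
                       consensus: float = 0.5) -> BinaryMap:
    """Majority vote over per-model cutoff exceedance.

    A pixel is habitat iff the fraction of models whose suitability is
    strictly above their own cutoff is strictly greater than
    ``consensus`` (default: more than 50% of models).
    """
    if len(model_maps) == 0:
        raise ValueError("need at least one model map")
    if len(model_maps) != len(cutoffs):
        raise ValueError("one cutoff per model map required")
    votes = np.zeros(model_maps[0].shape, dtype=float)
    for grid, cut in zip(model_maps, cutoffs):
        votes += (np.nan_to_num(grid, nan=-np.inf) > cut).astype(float)
    frac = votes / len(model_maps)
    return BinaryMap(grid=(frac > consensus).astype(float), mask=mask,
                     note=f"consensus>{consensus} of {len(model_maps)} models")


def binary_from_truth(suitability: np.ndarray, cutoff: float,
                      mask: np.ndarray) -> BinaryMap:
    """Threshold a suitability map at a cutoff (strict), e.g. a known truth."""
    grid = (np.nan_to_num(suitability, nan=-np.inf) > cutoff).astype(float)
    return BinaryMap(grid=grid, mask=mask, note=f"threshold>{cutoff}")


def classify_transitions(current: BinaryMap, future: BinaryMap) -> TransitionMap:
    """Per-pixel never/always/lost/gained classification."""
    if current.grid.shape != future.grid.shape:
        raise GridMismatchError("current and future maps differ in shape")
    if not np.array_equal(current.mask, future.mask):
        raise GridMismatchError("current and future maps differ in mask")
    cur = current.habitat
    fut = future.habitat
    classes = np.full(cur.shape, -1, dtype=int)
    classes[current.mask] = NEVER
    classes[cur & fut] = ALWAYS
    classes[cur & ~fut] = LOST
    classes[~cur & fut] = GAINED
    return TransitionMap(classes=classes, mask=current.mask.copy())


def range_change(transitions: TransitionMap, mode: str = "dispersal",
                 connectivity: int = 8) -> RangeChangeStats:
    """Range-change percentages relative to the current range.

    ``mode="dispersal"`` counts every gained pixel; ``mode="no_dispersal"``
    counts a gained pixel only when its connected patch in the future
    binary map contains at least one always-occupied pixel.
    """
    if mode not in ("dispersal", "no_dispersal"):
        raise ValueError("mode must be 'dispersal' or 'no_dispersal'")
    cls = transitions.classes
    n_always = int((cls == ALWAYS).sum())
    n_lost = int((cls == LOST).sum())
    n_gained = int((cls == GAINED).sum())
    n_current = n_always + n_lost
    if n_current == 0:
        raise EmptyRangeError("current range is empty; percentages undefined")

    if mode == "dispersal":
        n_counted = n_gained
    else:
        future = (cls == ALWAYS) | (cls == GAINED)
        labels, n_patches = ndimage.label(future, structure=_structure(connectivity))
        anchored = np.zeros(n_patches + 1, dtype=bool)
        anchored_ids = np.unique(labels[cls == ALWAYS])
        anchored[anchored_ids] = True
        counted = anchored[labels] & (cls == GAINED)
        n_counted = int(counted.sum())

    loss_pct = 100.0 * n_lost / n_current
    gain_pct = 100.0 * n_counted / n_current
    return RangeChangeStats(
        mode=mode, n_current=n_current, n_lost=n_lost, n_gained=n_gained,
        n_gained_counted=n_counted, loss_pct=loss_pct, gain_pct=gain_pct,
        net_change_pct=gain_pct - loss_pct)


def range_change_table(transitions: TransitionMap, species: str, scenario: str,
                       connectivity: int = 8) -> pd.DataFrame:
    rows = []
    for mode in ("dispersal", "no_dispersal"):
        s = range_change(transitions, mode=mode, connectivity=connectivity)
        rows.append({
            "species": species, "scenario": scenario, "mode": mode,
            "n_current": s.n_current, "n_lost": s.n_lost,
            "n_gained": s.n_gained, "n_gained_counted": s.n_gained_counted,
            "loss_pct": s.loss_pct, "gain_pct": s.gain_pct,
            "net_change_pct": s.net_change_pct,
        })
    return pd.DataFrame(rows)
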