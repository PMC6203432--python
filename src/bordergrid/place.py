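"""Place layer: 64 units with random grid afferents and uniform recurrent
inhibition."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

N_PLACE = 64
N_AFFERENTS = 500
RECURRENT_INHIB = -0.15
W_INIT_MAX = 0.022


@dataclass
class PlaceLayer:
    """Wiring and weights of the place population.

    ``afferents[j]`` lists the 500 grid-unit flat indices feeding place unit
    j (sampled without replacement, pooled across modules); ``w[j]`` holds
    the corresponding feed-forward weights.  Recurrent inhibition is uniform
    and all-to-all, including each unit onto itself.
    """

    afferents: np.ndarray  # (64, 500) int
    w: np.ndarray          # (64, 500) float
    inhib_weight: float = RECURRENT_INHIB
    a: np.ndarray | None = None

    def __post_init__(self):
        if self.a is None:
            self.a = np.zeros(len(self.afferents))

    @property
    def n_units(self) -> int:
        return len(self.afferents)


def init_place_layer(n_grid_units: int, seed=None, n_place: int = N_PLACE,
                     n_afferents: int = N_AFFERENTS,
                     w_init_max: float = W_INIT_MAX) -> PlaceLayer:
    """Draw afferent wiring and initial weights (uniform on [0, w_init_max])."""
    if n_grid_units < n_afferents:
        raise ValueError(
            f"grid population ({n_grid_units}) smaller than {n_afferents} afferents")
    rng = np.random.default_rng(seed)
    aff = np.empty((n_place, n_afferents), dtype=np.int64)
    for j in range(n_place):
        aff[j] = rng.choice(n_grid_units, size=n_afferents, replace=False)
    w = rng.uniform(0.0, w_init_max, size=(n_place, n_afferents))
    return PlaceLayer(afferents=aff, w=w)


def place_input(layer: PlaceLayer, grid_activations_flat: np.ndarray,
                place_activations: np.ndarray | None = None) -> np.ndarray:
    """Total input per place unit: grid afferent drive plus uniform recurrent
    inhibition from all place units (self included)."""
    if place_activations is None:
        place_activations = layer.a
    pre = grid_activations_flat[layer.afferents]
    drive = np.einsum("ij,ij->i", pre, layer.w)
    return drive + layer.inhib_weight * place_activations.sum()
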