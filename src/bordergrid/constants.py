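"""Network dynamics constants shared across layers."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class DynamicsConstants:
    """Timestep-level constants of the spiking dynamics and learning rule.

    ``kappa * dt = 1.5`` with the defaults, so any unit whose drive exceeds
    its threshold by 2/3 spikes with probability 1.
    """

    kappa: float = 500.0        # spike-probability scale
    dt_s: float = 0.003         # timestep
    alpha: float = 0.5          # activation increment per spike
    c_s: float = 0.03           # activation integration time constant
    beta_border: float = 0.0    # spike thresholds
    beta_grid: float = 0.1
    beta_place: float = 0.05
    lam: float = 1e-5           # Hebbian learning rate
    xi_border_grid: float = 0.4  # target summed weight, border -> grid
    xi_grid_place: float = 0.5   # target summed weight, grid -> place

    @property
    def decay(self) -> float:
        """Per-step activation retention factor (0.9 with the defaults)."""
        return 1.0 - self.dt_s / self.c_s


DEFAULTS = DynamicsConstants()
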