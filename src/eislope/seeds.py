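"""Deterministic seed fan-out.

A single master seed is expanded into named, statistically independent
streams via :class:`numpy.random.SeedSequence` spawn keys.  Wiring uses a
stream that depends only on (master, config) so connectivity is frozen
across trials of one configuration, while initial conditions and every
Poisson drive get fresh streams per trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# fixed sub-stream tags (spawn-key components)
_WIRING = 0
_INIT = 1
_DRIVE = 2


@dataclass(frozen=True)
class SeedBundle:
    """Seeds applied to one simulation: wiring, init, and per-drive streams."""

    master: int
    config_key: int = 0
    trial: int = 0
    _cache: dict = field(default_factory=dict, compare=False, repr=False)

    def _seq(self, *key: int) -> np.random.SeedSequence:
        return np.random.SeedSequence(entropy=self.master, spawn_key=key)

    def wiring_rng(self) -> np.random.Generator:
        return np.random.default_rng(self._seq(_WIRING, self.config_key))

    def init_rng(self) -> np.random.Generator:
        return np.random.default_rng(self._seq(_INIT, self.config_key, self.trial))

    def drive_rng(self, drive_index: int) -> np.random.Generator:
        return np.random.default_rng(self._seq(_DRIVE, self.config_key, self.trial, drive_index))

    def for_trial(self, trial: int) -> "SeedBundle":
        return SeedBundle(self.master, self.config_key, trial)

    def describe(self) -> dict:
        return {"master": self.master, "config_key": self.config_key, "trial": self.trial}
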