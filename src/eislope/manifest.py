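"""Run manifests: every output file traceable to a master seed and config."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path


def config_hash(config) -> str:
    """Stable hash of a NetworkConfig's canonical YAML form."""
    text = config.to_yaml() if hasattr(config, "to_yaml") else json.dumps(config, sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    experiment: str
    master_seed: int
    preset: str
    n_trials: int
    config_hashes: list[str] = field(default_factory=list)
    n_configs: int = 0
    outputs: dict = field(default_factory=dict)  # label -> path
    seeds: dict = field(default_factory=dict)
    versions: dict = field(default_factory=dict)
    wall_time_s: float = 0.0
    complete: bool = False
    started_at: float = field(default_factory=time.time)

    def finish(self) -> None:
        self.wall_time_s = time.time() - self.started_at
        self.complete = True

    def write(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def read(cls, path) -> "RunManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def package_versions() -> dict:
    import numpy, scipy, pandas, numba

    import eislope

    return {
        "eislope": eislope.__version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "numba": numba.__version__,
    }
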