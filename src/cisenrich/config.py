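"""Run configurations and their stable fingerprints."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

REGION_PRESETS = {
    "up1k": ("fixed", 1000, 0),
    "up10k": ("fixed", 10000, 0),
    "up5k": ("fixed", 5000, 0),
    "up5k-down2k": ("fixed", 5000, 2000),
    "nearest-tss": ("nearest_tss", 0, 0),
    "territory": ("territory", 0, 0),
}


@dataclass(frozen=True)
class RunConfiguration:
    """One combination of methodological options.

    ``fingerprint()`` hashes the canonicalized options, so two
    configurations share a fingerprint iff their options are identical.
    """

    normalization: str = "standard"       # standard | gc
    region: str = "up5k"                  # key of REGION_PRESETS
    conservation: bool = False
    accessibility: bool = False
    K: int = 500
    max_p: float = 0.05
    n_gc_bins: int = 20
    retain_fraction: float = 0.10
    window_length: int = 500
    shift: int = 250
    bg_order: int = 2
    pseudocount: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.normalization not in ("standard", "gc"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.region not in REGION_PRESETS:
            raise ValueError(
                f"unknown region {self.region!r}; "
                f"choose from {sorted(REGION_PRESETS)}")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if not 0 < self.max_p <= 1:
            raise ValueError("max_p must be in (0, 1]")
        if not 0 < self.retain_fraction <= 1:
            raise ValueError("retain_fraction must be in (0, 1]")

    def region_params(self) -> tuple[str, int, int]:
        return REGION_PRESETS[self.region]

    def canonical(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, separators=(",", ":"))

    def fingerprint(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:12]

    def replace(self, **kwargs) -> "RunConfiguration":
        d = asdict(self)
        d.update(kwargs)
        return RunConfiguration(**d)


def read_config_file(path: str) -> dict:
    """Flat key=value configuration file mirroring the CLI flags."""
    out: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value")
            key, value = (s.strip() for s in line.split("=", 1))
            out[key.replace("-", "_")] = value
    return out
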