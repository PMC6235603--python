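"""Network configuration: parameter defaults and flat key-value file I/O.

The defaults are the study conditions of the model: a diluted directed
network of N = 100 neurons (90 excitatory, 10 inhibitory) with average
in-degree 10, intrinsic excitabilities drawn from a flat distribution of
width 0.45 mV centred on the firing threshold with exactly 10% of the
neurons suprathreshold, and Gaussian synaptic parameters whose standard
deviation equals half the mean.  Subscripts follow the (postsynaptic,
presynaptic) convention: e.g. ``g_mean_ei`` is the coupling from an
inhibitory presynaptic cell onto an excitatory postsynaptic cell.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

from .constants import V_TH


class InvalidConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class NetworkConfig:
    n_total: int = 100
    n_exc: int = 90
    n_inh: int = 10
    mean_in_degree: float = 10.0
    excitability_center: float = V_TH
    #: half-width of the flat excitability distribution (support center +/- width)
    excitability_width: float = 0.45
    frac_suprathreshold: float = 0.10
    #: anti-correlate excitability with total structural degree
    correlated: bool = True
    seed: int = 0

    # synaptic parameter means; SD = sd_factor * mean for every entry
    t_decay_mean: float = 3.0          # T^I, ms, all synapses
    t_recovery_mean_epost: float = 800.0   # T^R, ms, onto excitatory post
    t_recovery_mean_ipost: float = 100.0   # T^R, ms, onto inhibitory post
    t_facil_mean: float = 1000.0       # T^F, ms, onto inhibitory post only
    u_mean_epost: float = 0.5          # U, onto excitatory post
    u_mean_ipost: float = 0.04         # U, onto inhibitory post
    g_mean_ee: float = 45.0            # |G|, mV, e <- e
    g_mean_ei: float = 135.0           # |G|, mV, e <- i
    g_mean_ie: float = 180.0           # |G|, mV, i <- e
    g_mean_ii: float = 180.0           # |G|, mV, i <- i
    sd_factor: float = 0.5

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_exc + self.n_inh != self.n_total:
            raise InvalidConfigError(
                f"n_exc + n_inh = {self.n_exc + self.n_inh} != n_total = {self.n_total}"
            )
        if not 0 < self.mean_in_degree < self.n_total:
            raise InvalidConfigError(
                f"mean_in_degree must lie in (0, n_total); got {self.mean_in_degree}"
            )
        if self.excitability_width <= 0:
            raise InvalidConfigError("excitability_width must be positive")
        if not 0 <= self.frac_suprathreshold <= 1:
            raise InvalidConfigError("frac_suprathreshold must lie in [0, 1]")
        if self.sd_factor < 0:
            raise InvalidConfigError("sd_factor must be non-negative")

    def to_file(self, path: str | Path) -> None:
        lines = ["# burstclique network configuration"]
        for f in dataclasses.fields(self):
            lines.append(f"{f.name} = {getattr(self, f.name)}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "NetworkConfig":
        known = {f.name: f.type for f in dataclasses.fields(cls)}
        kwargs: dict = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise InvalidConfigError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in known:
                raise InvalidConfigError(f"{path}:{lineno}: unknown key {key!r}")
            kwargs[key] = _parse_scalar(value)
        return cls(**kwargs)


def _parse_scalar(text: str):
    low = text.lower()
    if low in ("true", "false"):
        return low == "true"
    try:
        return int(text)
    except ValueError:
        pass
    try:
        return float(text)
    except ValueError:
        return text
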