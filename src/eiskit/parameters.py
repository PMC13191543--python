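"""Named circuit parameters with units, bounds and fixed/free flags."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterator, Mapping, Tuple

import numpy as np

__all__ = ["ParameterEntry", "ParameterSet", "DEFAULT_BOUNDS"]

# Wide physical bounds per parameter family; n is capped at the ideal-capacitor
# limit.  Keys are matched by prefix of the parameter name.
DEFAULT_BOUNDS: Dict[str, Tuple[float, float]] = {
    "R": (1e-6, 1e12),   # ohm
    "C": (1e-16, 1.0),   # farad
    "Y0": (1e-12, 1e6),  # S s^n
    "n": (1e-3, 1.0),    # dimensionless
    "W": (1e-12, 1e6),   # S s^1/2
}

_UNITS = {"R": "ohm", "C": "F", "Y0": "S s^n", "n": "", "W": "S s^1/2"}


def _family(name: str) -> str:
    """Parameter family from a name: R2 -> R, Y0_2 -> Y0, n_2 -> n."""
    base = name.split("_")[0]
    if base.startswith("Y0"):
        return "Y0"
    if base.startswith("CPE"):  # pragma: no cover - names never start with CPE
        return "Y0"
    if base[0] in "RCW" and (len(base) == 1 or base[1:].isdigit()):
        return base[0]
    if base == "n":
        return "n"
    raise ValueError(f"cannot infer parameter family of {name!r}")


@dataclass(frozen=True)
class ParameterEntry:
    value: float
    lower: float
    upper: float
    fixed: bool = False
    unit: str = ""

    def __post_init__(self) -> None:
        if not (self.lower <= self.value <= self.upper):
            raise ValueError(
                f"value {self.value!r} outside bounds [{self.lower!r}, {self.upper!r}]"
            )
        if self.lower <= 0:
            raise ValueError("bounds must keep parameters strictly positive")


class ParameterSet:
    """Ordered mapping of parameter name -> :class:`ParameterEntry`.

    Construct from a plain ``{name: value}`` mapping (bounds filled from
    :data:`DEFAULT_BOUNDS` by family) or from explicit entries.
    """

    def __init__(self, entries: Mapping[str, ParameterEntry]):
        self._entries: Dict[str, ParameterEntry] = dict(entries)

    @classmethod
    def from_values(
        cls,
        values: Mapping[str, float],
        bounds: Mapping[str, Tuple[float, float]] | None = None,
        fixed: Mapping[str, bool] | None = None,
    ) -> "ParameterSet":
        entries = {}
        for name, value in values.items():
            fam = _family(name)
            lo, hi = (bounds or {}).get(name, DEFAULT_BOUNDS[fam])
            entries[name] = ParameterEntry(
                value=float(value),
                lower=lo,
                upper=hi,
                fixed=bool((fixed or {}).get(name, False)),
                unit=_UNITS[fam],
            )
        return cls(entries)

    # -- mapping protocol -------------------------------------------------
    def __getitem__(self, name: str) -> float:
        return self._entries[name].value

    def __contains__(self, name: str) -> bool:
        return name in self._entries

    def __iter__(self) -> Iterator[str]:
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def __repr__(self) -> str:
        body = ", ".join(f"{k}={e.value:.6g}" for k, e in self._entries.items())
        return f"ParameterSet({body})"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ParameterSet):
            return NotImplemented
        return self._entries == other._entries

    # -- accessors --------------------------------------------------------
    def entry(self, name: str) -> ParameterEntry:
        return self._entries[name]

    @property
    def names(self) -> Tuple[str, ...]:
        return tuple(self._entries)

    @property
    def free_names(self) -> Tuple[str, ...]:
        return tuple(k for k, e in self._entries.items() if not e.fixed)

    def values_dict(self) -> Dict[str, float]:
        return {k: e.value for k, e in self._entries.items()}

    def free_values(self) -> np.ndarray:
        return np.array([self._entries[k].value for k in self.free_names], float)

    # -- functional updates ------------------------------------------------
    def with_values(self, values: Mapping[str, float]) -> "ParameterSet":
        entries = dict(self._entries)
        for name, value in values.items():
            entries[name] = replace(entries[name], value=float(value))
        return ParameterSet(entries)

    def with_free_values(self, vector: np.ndarray) -> "ParameterSet":
        return self.with_values(dict(zip(self.free_names, vector)))

    def scaled(self, factor: float) -> "ParameterSet":
        """Every free value multiplied by ``factor``, clipped inside its bounds.

        Used to perturb initial guesses in recovery experiments.
        """
        entries = dict(self._entries)
        for name in self.free_names:
            e = entries[name]
            v = float(np.clip(e.value * factor, np.nextafter(e.lower, np.inf),
                              np.nextafter(e.upper, -np.inf)))
            entries[name] = replace(e, value=v)
        return ParameterSet(entries)
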