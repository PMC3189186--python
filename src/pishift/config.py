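"""Run configuration: flat key=value files with documented defaults."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

__all__ = ["Config", "load_config", "load_keyvalue_file"]


@dataclass
class Config:
    """All tunables of the analysis, with their defaults.

    The pKa scale, the quantile convention of the shift threshold, the
    phospho charge model, and the bisection precision default to the
    values used by the built-in analysis; everything else is plumbing.
    """

    pka_table: str = "builtin"
    quantile_convention: str = "linear"  # order statistics at (k-1)/(n-1)
    bounds_low: float = 6.8
    bounds_high: float = 7.2
    alpha: float = 0.05
    n_perm: int = 1000
    perm_mode: str = "protein"
    seed: int = 42
    precision: float = 0.01
    phospho_pka1: float = 1.2
    phospho_pka2: float = 6.5
    sialic_per_glyco: int = 0
    sialic_pka: float = 2.6
    use_ptms: bool = False
    header_delimiter: str = "|"

    def __post_init__(self) -> None:
        if not self.bounds_low < self.bounds_high:
            raise ValueError("bounds_low must be < bounds_high")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.perm_mode not in ("protein", "threshold"):
            raise ValueError("perm_mode must be 'protein' or 'threshold'")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")

    def as_dict(self) -> dict:
        return asdict(self)


def _coerce(raw: str, target_type: type):
    if target_type is bool:
        lowered = raw.strip().lower()
        if lowered in ("1", "true", "yes", "on"):
            return True
        if lowered in ("0", "false", "no", "off"):
            return False
        raise ValueError(f"cannot parse boolean from {raw!r}")
    return target_type(raw)


def load_keyvalue_file(path: str | Path) -> dict:
    """Parse a flat ``key = value`` file ('#' starts a comment)."""
    result: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        stripped = line.split("#", 1)[0].strip()
        if not stripped:
            continue
        if "=" not in stripped:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, value = stripped.split("=", 1)
        result[key.strip()] = value.strip()
    return result


def load_config(path: str | Path | None) -> Config:
    """Load a :class:`Config`, applying defaults for unspecified keys."""
    if path is None:
        return Config()
    raw = load_keyvalue_file(path)
    known = {f.name: f.type for f in fields(Config)}
    types = {
        "pka_table": str, "quantile_convention": str, "bounds_low": float,
        "bounds_high": float, "alpha": float, "n_perm": int, "perm_mode": str,
        "seed": int, "precision": float, "phospho_pka1": float, "phospho_pka2": float,
        "sialic_per_glyco": int, "sialic_pka": float, "use_ptms": bool,
        "header_delimiter": str,
    }
    kwargs = {}
    for key, value in raw.items():
        if key not in known:
            raise ValueError(f"unknown config key {key!r}")
        kwargs[key] = _coerce(value, types[key])
    return Config(**kwargs)
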