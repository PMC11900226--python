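"""Run configuration: flat TOML sections with strict key validation.

Sections and keys::

    seed = 0                  # top-level, optional
    [model]                   # ModelParams keys
    t0, r_ref, zeta, u_onsite, ohno_a, core_amp, core_rho, hop_cutoff, n_electrons
    [bse]
    screening ("rpa"|"bare"), scissor (Ry), spin ("singlet"|"triplet"),
    n_states, solver ("dense"|"davidson"), davidson_tol,
    qp_shift_file (two-column text: orbital index, shift in Ry)
    [forces]
    delta_lambda (Bohr)
    [optimize]
    algorithm ("bfgs"|"sd"), fmax (Ry/Bohr), max_steps, step_init

Unknown keys or sections raise :class:`ConfigError`.  Defaults are
materialized on load so every output file can echo the fully resolved
configuration.
"""

from __future__ import annotations

import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .forces import BseSettings, DEFAULT_DELTA_LAMBDA, DEFAULT_FMAX
from .model import ModelParams

__all__ = ["ConfigError", "RunConfig", "load_config", "read_qp_shift_table"]


class ConfigError(ValueError):
    """Invalid configuration file content."""


_MODEL_KEYS = {
    "t0", "r_ref", "zeta", "u_onsite", "ohno_a",
    "core_amp", "core_rho", "hop_cutoff", "n_electrons",
}
_BSE_KEYS = {
    "screening", "scissor", "spin", "n_states", "solver", "davidson_tol", "qp_shift_file",
}
_FORCES_KEYS = {"delta_lambda"}
_OPTIMIZE_KEYS = {"algorithm", "fmax", "max_steps", "step_init"}


def read_qp_shift_table(path) -> dict[int, float]:
    """Two-column plain text: absolute orbital index (0-based) and shift in Ry."""
    shifts: dict[int, float] = {}
    for ln_no, ln in enumerate(Path(path).read_text().splitlines(), 1):
        stripped = ln.split("#")[0].strip()
        if not stripped:
            continue
        parts = stripped.split()
        if len(parts) != 2:
            raise ConfigError(f"{path}:{ln_no}: expected 'orbital_index shift', got {ln!r}")
        shifts[int(parts[0])] = float(parts[1])
    return shifts


@dataclass
class RunConfig:
    model: ModelParams = field(default_factory=ModelParams)
    screening: str = "rpa"
    scissor: float = 0.0
    spin: str = "singlet"
    n_states: int = 3
    solver: str = "dense"
    davidson_tol: float = 1e-10
    qp_shifts: dict[int, float] = field(default_factory=dict)
    delta_lambda: float = DEFAULT_DELTA_LAMBDA
    algorithm: str = "bfgs"
    fmax: float = DEFAULT_FMAX
    max_steps: int = 60
    step_init: float = 0.5
    seed: int = 0

    def bse_settings(self, n_valence: int) -> BseSettings:
        """Split the absolute-index QP shift table at the Fermi level."""
        val = {i: s for i, s in self.qp_shifts.items() if i < n_valence}
        cond = {i: s for i, s in self.qp_shifts.items() if i >= n_valence}
        return BseSettings(
            screening=self.screening,
            scissor=self.scissor,
            spin=self.spin,
            n_states=self.n_states,
            solver=self.solver,
            davidson_tol=self.davidson_tol,
            valence_shifts=val,
            conduction_shifts=cond,
        )

    def resolved(self) -> dict:
        """Fully materialized configuration for echoing into output files."""
        return {
            "seed": self.seed,
            "model": asdict(self.model),
            "bse": {
                "screening": self.screening,
                "scissor": self.scissor,
                "spin": self.spin,
                "n_states": self.n_states,
                "solver": self.solver,
                "davidson_tol": self.davidson_tol,
                "qp_shifts": {str(k): v for k, v in sorted(self.qp_shifts.items())},
            },
            "forces": {"delta_lambda": self.delta_lambda},
            "optimize": {
                "algorithm": self.algorithm,
                "fmax": self.fmax,
                "max_steps": self.max_steps,
                "step_init": self.step_init,
            },
        }


def _check_keys(section: str, data: dict, allowed: set[str]) -> None:
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in section [{section}]; "
            f"allowed: {sorted(allowed)}"
        )


def load_config(path=None, base_dir=None) -> RunConfig:
    """Load a TOML config file; ``path=None`` yields all defaults."""
    cfg = RunConfig()
    if path is None:
        return cfg
    path = Path(path)
    try:
        data = tomllib.loads(path.read_text())
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    _check_keys("<top>", data, {"model", "bse", "forces", "optimize", "seed"})
    if "seed" in data:
        cfg.seed = int(data["seed"])
    model = data.get("model", {})
    _check_keys("model", model, _MODEL_KEYS)
    if model:
        cfg.model = ModelParams(**{k: (int(v) if k == "n_electrons" else float(v)) for k, v in model.items()})
    bse = data.get("bse", {})
    _check_keys("bse", bse, _BSE_KEYS)
    if "screening" in bse:
        if bse["screening"] not in ("rpa", "bare"):
            raise ConfigError(f"screening must be 'rpa' or 'bare', got {bse['screening']!r}")
        cfg.screening = bse["screening"]
    if "spin" in bse:
        if bse["spin"] not in ("singlet", "triplet"):
            raise ConfigError(f"spin must be 'singlet' or 'triplet', got {bse['spin']!r}")
        cfg.spin = bse["spin"]
    if "solver" in bse:
        if bse["solver"] not in ("dense", "davidson"):
            raise ConfigError(f"solver must be 'dense' or 'davidson', got {bse['solver']!r}")
        cfg.solver = bse["solver"]
    cfg.scissor = float(bse.get("scissor", cfg.scissor))
    cfg.n_states = int(bse.get("n_states", cfg.n_states))
    cfg.davidson_tol = float(bse.get("davidson_tol", cfg.davidson_tol))
    if "qp_shift_file" in bse:
        shift_path = Path(bse["qp_shift_file"])
        if not shift_path.is_absolute():
            shift_path = (Path(base_dir) if base_dir else path.parent) / shift_path
        cfg.qp_shifts = read_qp_shift_table(shift_path)
    forces = data.get("forces", {})
    _check_keys("forces", forces, _FORCES_KEYS)
    cfg.delta_lambda = float(forces.get("delta_lambda", cfg.delta_lambda))
    opt = data.get("optimize", {})
    _check_keys("optimize", opt, _OPTIMIZE_KEYS)
    if "algorithm" in opt:
        if opt["algorithm"] not in ("bfgs", "sd"):
            raise ConfigError(f"algorithm must be 'bfgs' or 'sd', got {opt['algorithm']!r}")
        cfg.algorithm = opt["algorithm"]
    cfg.fmax = float(opt.get("fmax", cfg.fmax))
    cfg.max_steps = int(opt.get("max_steps", cfg.max_steps))
    cfg.step_init = float(opt.get("step_init", cfg.step_init))
    return cfg
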