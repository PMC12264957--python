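"""Workflow configuration: a TOML dialect with repeated module sections.

The file starts with global parameters (run directory, input molecules,
seed, execution mode), followed by one section per workflow step in
execution order.  Standard TOML forbids repeating a table name, so the
single dialect extension is that module sections *may* repeat — e.g. a
second ``[caprieval]`` later in the workflow.  Repeats are normalized to
internal step ids ``name__2``, ``name__3`` ... before TOML parsing; the
explicit suffixed form is also accepted.
"""

from __future__ import annotations

import difflib
import re
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from .registry import MODULE_REGISTRY, ModuleSpec

__all__ = ["ConfigError", "Step", "WorkflowConfig", "parse_config",
           "validate_config", "load_config"]

_GLOBAL_KEYS = {"run_dir", "molecules", "mode", "ncores", "seed"}
_SECTION_RE = re.compile(r"^\s*\[([A-Za-z0-9_]+)\]\s*(?:#.*)?$")
_SUFFIX_RE = re.compile(r"^(.*?)__([0-9]+)$")


class ConfigError(ValueError):
    """Invalid workflow configuration."""


@dataclass
class Step:
    module: str                  # registry module name
    step_id: str                 # unique per workflow (name or name__k)
    params: dict[str, Any] = field(default_factory=dict)


@dataclass
class WorkflowConfig:
    run_dir: Path
    molecules: list[Path]
    steps: list[Step]
    mode: str = "local"
    ncores: int = 1
    seed: int = 42
    source: Path | None = None


def module_of(step_id: str) -> str:
    m = _SUFFIX_RE.match(step_id)
    return m.group(1) if m else step_id


def _normalize_sections(text: str) -> str:
    """Rename repeated top-level module sections to unique step ids."""
    counts: dict[str, int] = {}
    out: list[str] = []
    for line in text.splitlines():
        m = _SECTION_RE.match(line)
        if m:
            name = m.group(1)
            base = module_of(name)
            counts[base] = counts.get(base, 0) + 1
            if counts[base] > 1 and name == base:
                line = line.replace(f"[{name}]",
                                    f"[{base}__{counts[base]}]", 1)
        out.append(line)
    return "\n".join(out)


def parse_config(path: str | Path) -> WorkflowConfig:
    """Parse a workflow file into globals + the ordered step list.

    Global keys come first; each subsequent section is one step, in file
    order.  Syntax errors carry the TOML parser's position; a repeated
    global key is an error.
    """
    path = Path(path)
    text = path.read_text()
    try:
        data = tomllib.loads(_normalize_sections(text))
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc

    steps: list[Step] = []
    run_globals: dict[str, Any] = {}
    for key, value in data.items():           # insertion order = file order
        if isinstance(value, dict):
            steps.append(Step(module=module_of(key), step_id=key,
                              params=dict(value)))
        else:
            if key not in _GLOBAL_KEYS:
                hint = difflib.get_close_matches(key, _GLOBAL_KEYS, n=1)
                extra = f"; did you mean {hint[0]!r}?" if hint else ""
                raise ConfigError(
                    f"{path}: unknown global parameter {key!r}{extra}")
            run_globals[key] = value

    if "run_dir" not in run_globals:
        raise ConfigError(f"{path}: missing required global 'run_dir'")
    if "molecules" not in run_globals:
        raise ConfigError(f"{path}: missing required global 'molecules'")
    molecules = run_globals["molecules"]
    if isinstance(molecules, str):
        molecules = [molecules]
    return WorkflowConfig(
        run_dir=Path(run_globals["run_dir"]),
        molecules=[Path(m) for m in molecules],
        steps=steps,
        mode=run_globals.get("mode", "local"),
        ncores=int(run_globals.get("ncores", 1)),
        seed=int(run_globals.get("seed", 42)),
        source=path,
    )


def validate_config(config: WorkflowConfig,
                    registry: dict[str, ModuleSpec] | None = None
                    ) -> WorkflowConfig:
    """Check a parsed config against the module registry.

    Verifies module names, parameter names (with nearest-name
    suggestions), parameter types, input file existence and the
    topology-first rule; injects defaults for omitted parameters.
    """
    registry = registry or MODULE_REGISTRY
    if not config.steps:
        raise ConfigError("workflow has no steps")
    if config.mode != "local":
        raise ConfigError(f"unsupported execution mode {config.mode!r}; "
                          f"only 'local' is available")
    first = config.steps[0]
    if first.module not in registry:
        _unknown_module(first.module, registry)
    if registry[first.module].category != "topology":
        raise ConfigError(
            f"the first step must be a topology module, got "
            f"{first.module!r}")

    base = config.source.parent if config.source else Path(".")
    for mol in config.molecules:
        if not _resolve(base, mol).exists():
            raise ConfigError(f"input molecule not found: {mol}")
    if not config.molecules:
        raise ConfigError("no input molecules")

    seen_ids: set[str] = set()
    for step in config.steps:
        if step.module not in registry:
            _unknown_module(step.module, registry)
        if step.step_id in seen_ids:
            raise ConfigError(f"duplicate step id {step.step_id!r}")
        seen_ids.add(step.step_id)
        spec = registry[step.module]
        for pname, value in step.params.items():
            if pname not in spec.params:
                hint = difflib.get_close_matches(pname, spec.params, n=1)
                extra = f"; did you mean {hint[0]!r}?" if hint else ""
                raise ConfigError(
                    f"step {step.step_id!r}: unknown parameter "
                    f"{pname!r}{extra}")
            if not spec.params[pname].check(value):
                raise ConfigError(
                    f"step {step.step_id!r}: parameter {pname!r} expects "
                    f"{spec.params[pname].type.__name__}, got {value!r}")
        for pname, p in spec.params.items():
            step.params.setdefault(
                pname, list(p.default) if isinstance(p.default, list)
                else p.default)
        # restraint / reference paths must exist up front
        for key in ("ambig_fname", "unambig_fname", "reference_fname"):
            val = step.params.get(key)
            if not val:
                continue
            paths = val if isinstance(val, list) else [val]
            for p in paths:
                if not _resolve(base, Path(p)).exists():
                    raise ConfigError(
                        f"step {step.step_id!r}: file not found for "
                        f"{key}: {p}")
    return config


def _resolve(base: Path, p: Path) -> Path:
    return p if p.is_absolute() else base / p


def _unknown_module(name: str, registry: dict[str, ModuleSpec]) -> None:
    hint = difflib.get_close_matches(name, registry, n=1)
    extra = f"; did you mean {hint[0]!r}?" if hint else ""
    raise ConfigError(f"unknown module {name!r}{extra}")


def load_config(path: str | Path) -> WorkflowConfig:
    """Parse and validate in one call."""
    return validate_config(parse_config(path))
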