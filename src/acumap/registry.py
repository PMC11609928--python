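"""Catalog of acupoints and the declarative mapping rule attached to each.

Rules are data, not code: a small step language (anchor / midpoint /
fraction / toward) stored in a versioned YAML table and evaluated by
:mod:`acumap.mapping`. The shipped default table defines 38 acupoints,
18 on the hand and 20 on the face.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Union

import yaml

from .errors import LookupError_, RegistryError
from .landmarks import SLOT_COUNTS
from .posture import FACE_POSES, HAND_POSTURES

RULE_SCHEMA = "acumap-rules/1"

REGION_POSTURES = {"hand": HAND_POSTURES, "face": FACE_POSES}

_STEP_FIELDS = {
    "anchor": {"landmark"},
    "midpoint": {"a", "b"},
    "fraction": {"a", "b", "t"},
    "toward": {"origin", "target", "scale", "base"},
}

Ref = tuple[str, int]  # ("landmark", i) or ("step", j)


def parse_ref(token: str) -> Ref:
    """Parse a step-language reference: "L5" (landmark) or "S0" (step)."""
    if isinstance(token, str) and len(token) >= 2 and token[0] in ("L", "S"):
        try:
            idx = int(token[1:])
        except ValueError:
            pass
        else:
            if idx >= 0:
                return ("landmark" if token[0] == "L" else "step", idx)
    raise RegistryError(f"malformed reference {token!r} (expected 'L<i>' or 'S<j>')")


def format_ref(ref: Ref) -> str:
    kind, idx = ref
    return ("L" if kind == "landmark" else "S") + str(idx)


@dataclass(frozen=True)
class RuleStep:
    """One step of a mapping rule; ``params`` keys depend on ``op``."""

    op: str
    params: tuple[tuple[str, object], ...]

    @classmethod
    def from_dict(cls, raw: dict, where: str) -> "RuleStep":
        if not isinstance(raw, dict) or "op" not in raw:
            raise RegistryError(f"{where}: step must be a mapping with an 'op' key")
        op = raw["op"]
        if op not in _STEP_FIELDS:
            raise RegistryError(f"{where}: unknown step op {op!r}")
        keys = set(raw) - {"op"}
        if keys != _STEP_FIELDS[op]:
            raise RegistryError(
                f"{where}: step {op!r} takes fields {sorted(_STEP_FIELDS[op])}, "
                f"got {sorted(keys)}"
            )
        params: dict[str, object] = {}
        if op == "anchor":
            params["landmark"] = int(raw["landmark"])
        elif op == "midpoint":
            params["a"] = parse_ref(raw["a"])
            params["b"] = parse_ref(raw["b"])
        elif op == "fraction":
            params["a"] = parse_ref(raw["a"])
            params["b"] = parse_ref(raw["b"])
            params["t"] = float(raw["t"])
        elif op == "toward":
            params["origin"] = parse_ref(raw["origin"])
            params["target"] = parse_ref(raw["target"])
            params["scale"] = float(raw["scale"])
            base = raw["base"]
            if not (isinstance(base, (list, tuple)) and len(base) == 2):
                raise RegistryError(f"{where}: 'base' must be a pair of slot indices")
            params["base"] = (int(base[0]), int(base[1]))
        return cls(op=op, params=tuple(sorted(params.items())))

    def get(self, key: str) -> object:
        return dict(self.params)[key]

    def to_dict(self) -> dict:
        out: dict[str, object] = {"op": self.op}
        for key, value in self.params:
            if isinstance(value, tuple) and value and value[0] in ("landmark", "step"):
                out[key] = format_ref(value)  # type: ignore[arg-type]
            elif key == "base":
                out[key] = list(value)  # type: ignore[arg-type]
            else:
                out[key] = value
        return out

    def landmark_indices(self) -> Iterable[int]:
        for key, value in self.params:
            if key == "landmark":
                yield value  # type: ignore[misc]
            elif key == "base":
                yield from value  # type: ignore[misc]
            elif isinstance(value, tuple) and value and value[0] == "landmark":
                yield value[1]  # type: ignore[misc]

    def step_refs(self) -> Iterable[int]:
        for _, value in self.params:
            if isinstance(value, tuple) and value and value[0] == "step":
                yield value[1]  # type: ignore[misc]

    def constants(self) -> Iterable[float]:
        for key, value in self.params:
            if key in ("t", "scale"):
                yield value  # type: ignore[misc]


@dataclass(frozen=True)
class MappingRule:
    """An ordered list of steps; the last step's point is the result."""

    steps: tuple[RuleStep, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.steps:
            raise RegistryError("a mapping rule needs at least one step")

    def landmark_indices(self) -> set[int]:
        out: set[int] = set()
        for step in self.steps:
            out.update(step.landmark_indices())
        return out


@dataclass(frozen=True)
class AcupointDef:
    """One registry entry: identity plus per-posture rules."""

    code: str
    name: str
    meridian: str
    region: str
    rules: tuple[tuple[str, MappingRule], ...]  # (posture label, rule)

    def rule_for(self, posture: str) -> Optional[MappingRule]:
        for label, rule in self.rules:
            if label == posture:
                return rule
        return None

    @property
    def postures(self) -> tuple[str, ...]:
        return tuple(label for label, _ in self.rules)


@dataclass(frozen=True)
class ValidationIssue:
    code: str
    message: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def add(self, code: str, message: str) -> None:
        self.issues.append(ValidationIssue(code, message))


@dataclass(frozen=True)
class Registry:
    """Validated, ordered collection of acupoint definitions."""

    entries: tuple[AcupointDef, ...]
    version: str = "0"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for entry in self.entries:
            if entry.code in seen:
                raise RegistryError(f"duplicate acupoint code {entry.code!r}")
            seen.add(entry.code)

    def __len__(self) -> int:
        return len(self.entries)

    def codes(self) -> list[str]:
        return [e.code for e in self.entries]

    def get(self, code: str) -> AcupointDef:
        for entry in self.entries:
            if entry.code == code:
                return entry
        raise LookupError_(f"unknown acupoint code {code!r}")

    def region_entries(self, region: str) -> list[AcupointDef]:
        return [e for e in self.entries if e.region == region]


def _parse_entry(raw: dict, pos: int) -> AcupointDef:
    where = f"acupoints[{pos}]"
    if not isinstance(raw, dict):
        raise RegistryError(f"{where}: entry must be a mapping")
    missing = {"code", "name", "meridian", "region", "rules"} - set(raw)
    if missing:
        raise RegistryError(f"{where}: missing fields {sorted(missing)}")
    code = str(raw["code"])
    where = f"acupoints[{pos}] ({code})"
    region = str(raw["region"])
    if region not in SLOT_COUNTS:
        raise RegistryError(f"{where}: unknown region {region!r}")
    blocks = raw["rules"]
    if not isinstance(blocks, list) or not blocks:
        raise RegistryError(f"{where}: 'rules' must be a non-empty list")
    pairs: list[tuple[str, MappingRule]] = []
    for bi, block in enumerate(blocks):
        bwhere = f"{where}.rules[{bi}]"
        if not isinstance(block, dict) or "postures" not in block or "steps" not in block:
            raise RegistryError(f"{bwhere}: rule block needs 'postures' and 'steps'")
        steps = tuple(
            RuleStep.from_dict(s, f"{bwhere}.steps[{si}]")
            for si, s in enumerate(block["steps"])
        )
        rule = MappingRule(steps=steps, provenance=str(block.get("provenance", "")).strip())
        for label in block["postures"]:
            if any(label == existing for existing, _ in pairs):
                raise RegistryError(f"{bwhere}: duplicate posture {label!r} for {code}")
            pairs.append((str(label), rule))
    return AcupointDef(
        code=code,
        name=str(raw["name"]),
        meridian=str(raw["meridian"]),
        region=region,
        rules=tuple(pairs),
    )


def default_rule_table_path() -> Path:
    return Path(str(resources.files("acumap").joinpath("data/acupoint_rules.yaml")))


def load_registry(source: Union[str, Path, None] = None) -> Registry:
    """Load and validate a rule table; ``None`` loads the shipped default."""
    path = default_rule_table_path() if source is None else Path(source)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise RegistryError(f"cannot parse rule table {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise RegistryError(f"rule table {path} must be a YAML mapping")
    if raw.get("schema") != RULE_SCHEMA:
        raise RegistryError(
            f"rule table {path}: expected schema {RULE_SCHEMA!r}, got {raw.get('schema')!r}"
        )
    entries_raw = raw.get("acupoints", [])
    if entries_raw is None:
        entries_raw = []
    if not isinstance(entries_raw, list):
        raise RegistryError("'acupoints' must be a list")
    if not entries_raw:
        warnings.warn("loaded an empty acupoint registry", stacklevel=2)
    entries = tuple(_parse_entry(e, i) for i, e in enumerate(entries_raw))
    registry = Registry(entries=entries, version=str(raw.get("version", "0")))
    report = validate_registry(registry)
    if not report.ok:
        first = report.issues[0]
        raise RegistryError(
            f"rule table {path} failed validation "
            f"({len(report.issues)} issue(s); first: [{first.code}] {first.message})"
        )
    return registry


def save_registry(registry: Registry, path: Union[str, Path]) -> None:
    """Write a registry back to the YAML rule-table format."""
    doc = {
        "schema": RULE_SCHEMA,
        "version": registry.version,
        "acupoints": [],
    }
    for entry in registry.entries:
        blocks: list[dict] = []
        for label, rule in entry.rules:
            for block in blocks:
                if block["_rule"] is rule:
                    block["postures"].append(label)
                    break
            else:
                blocks.append(
                    {
                        "postures": [label],
                        "provenance": rule.provenance,
                        "steps": [s.to_dict() for s in rule.steps],
                        "_rule": rule,
                    }
                )
        for block in blocks:
            del block["_rule"]
        doc["acupoints"].append(
            {
                "code": entry.code,
                "name": entry.name,
                "meridian": entry.meridian,
                "region": entry.region,
                "rules": blocks,
            }
        )
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False, allow_unicode=True))


def rules_for(registry: Registry, code: str, posture: str) -> Optional[MappingRule]:
    """Rule for one acupoint under one posture; ``None`` = not visible there.

    Raises :class:`LookupError_` for an unknown code.
    """
    return registry.get(code).rule_for(posture)


def validate_registry(registry: Registry) -> ValidationReport:
    """Structural validation: index ranges, posture labels, finite constants."""
    report = ValidationReport()
    for entry in registry.entries:
        slot_count = SLOT_COUNTS[entry.region]
        allowed = REGION_POSTURES[entry.region]
        if not entry.rules:
            report.add("no-rules", f"{entry.code}: no rules defined")
        for label, rule in entry.rules:
            if label not in allowed:
                report.add(
                    "bad-posture",
                    f"{entry.code}: posture {label!r} invalid for region {entry.region}",
                )
            for si, step in enumerate(rule.steps):
                for idx in step.landmark_indices():
                    if not (0 <= idx < slot_count):
                        report.add(
                            "index-range",
                            f"{entry.code} [{label}] step {si}: landmark {idx} "
                            f"out of range 0-{slot_count - 1}",
                        )
                for sref in step.step_refs():
                    if sref >= si:
                        report.add(
                            "step-ref",
                            f"{entry.code} [{label}] step {si}: forward/self "
                            f"reference S{sref}",
                        )
                for const in step.constants():
                    if not math.isfinite(const):
                        report.add(
                            "non-finite",
                            f"{entry.code} [{label}] step {si}: non-finite constant",
                        )
    return report


def export_summary_csv(registry: Registry, path: Union[str, Path]) -> None:
    """CSV overview: code, name, meridian, region, postures covered."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["code", "name", "meridian", "region", "postures"])
        for entry in registry.entries:
            writer.writerow(
                [entry.code, entry.name, entry.meridian, entry.region,
                 "|".join(entry.postures)]
            )
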