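"""Scenario configuration files: loading, dotted-path access, overrides.

A scenario file is a YAML document mirroring the model's input tables:
transition probabilities, health-state costs and utilities, trastuzumab
acquisition inputs, trial hazard ratios, discount rates and a life-table
reference.  Every numeric leaf may be written either as a bare number
(treated as fixed) or as a ``{mean, se, family}`` map declaring its
probabilistic-sensitivity-analysis distribution.
"""

from __future__ import annotations

import copy
import hashlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import yaml

from .errors import ConfigurationError
from .parameters import LifeTable, ParameterDistribution

__all__ = ["ScenarioConfig", "bundled_config_path", "published_base_case"]

_MISSING = object()


def _config_dir():
    return resources.files("hercea") / "configs"


def bundled_config_path(name: str) -> Path:
    """Path of a bundled scenario/data file (``real_world``, ``guideline``, ...)."""
    f = _config_dir() / (name if "." in name else f"{name}.yaml")
    with resources.as_file(f) as p:
        return Path(p)


def _is_dist_node(node) -> bool:
    return isinstance(node, Mapping) and "mean" in node


@dataclass
class ScenarioConfig:
    """A loaded scenario configuration.

    Attributes
    ----------
    raw : dict
        The parsed YAML tree (numbers and distribution maps).
    life_table : LifeTable
        Background all-cause mortality for women, resolved at load time.
    name : str
        Scenario label (``real_world``, ``guideline`` or ``trial``).
    """

    raw: dict
    life_table: LifeTable
    name: str
    source: str = "<memory>"

    # -- loading -----------------------------------------------------------
    @classmethod
    def load(cls, source: str | Path) -> "ScenarioConfig":
        """Load a bundled scenario by name or any YAML file by path."""
        if isinstance(source, str) and "/" not in source and not source.endswith(".yaml"):
            path = bundled_config_path(source)
        else:
            path = Path(source)
        if not path.exists():
            raise ConfigurationError(f"scenario config not found: {source}")
        raw = yaml.safe_load(path.read_text())
        if not isinstance(raw, dict):
            raise ConfigurationError(f"malformed scenario config: {path}")
        return cls.from_dict(raw, base_dir=path.parent,
                             source=str(path))

    @classmethod
    def from_dict(cls, raw: dict, base_dir: Path | None = None,
                  source: str = "<memory>") -> "ScenarioConfig":
        lt_ref = raw.get("life_table")
        if lt_ref is None:
            raise ConfigurationError("config must reference a life_table file")
        if isinstance(lt_ref, Mapping):  # inline {ages: [...], q: [...]}
            life_table = LifeTable(np.asarray(lt_ref["ages"]),
                                   np.asarray(lt_ref["q"]))
        else:
            lt_path = Path(lt_ref)
            if not lt_path.is_absolute():
                candidates = [
                    (base_dir / lt_path) if base_dir else None,
                    bundled_config_path(str(lt_ref)),
                ]
                for c in candidates:
                    if c is not None and c.exists():
                        lt_path = c
                        break
            life_table = LifeTable.from_csv(lt_path)
        name = str(raw.get("scenario", "custom"))
        return cls(raw=raw, life_table=life_table, name=name, source=source)

    # -- dotted-path access ------------------------------------------------
    def node(self, path: str, default=_MISSING):
        cur = self.raw
        for part in path.split("."):
            if not isinstance(cur, Mapping) or part not in cur:
                if default is _MISSING:
                    raise ConfigurationError(
                        f"missing configuration field {path!r} in {self.source}")
                return default
            cur = cur[part]
        return cur

    def distribution(self, path: str) -> ParameterDistribution:
        return ParameterDistribution.from_spec(self.node(path))

    def value(self, path: str, draw: Mapping[str, float] | None = None,
              default=_MISSING):
        """Resolve a numeric leaf: drawn value if present, otherwise the mean."""
        if draw is not None and path in draw:
            return float(draw[path])
        node = self.node(path, default=default)
        if node is default and default is not _MISSING:
            return node
        if _is_dist_node(node):
            return float(node["mean"])
        if isinstance(node, (int, float)):
            return float(node)
        raise ConfigurationError(f"field {path!r} is not numeric")

    # -- distributions -----------------------------------------------------
    def distributions(self) -> Iterator[tuple[str, ParameterDistribution]]:
        """Yield every probabilistic leaf in a fixed, documented order.

        The order is the depth-first order of the YAML document; the
        probabilistic-sensitivity-analysis sampler consumes random draws in
        exactly this order, which makes runs reproducible from the seed.
        """
        def walk(node, prefix):
            if _is_dist_node(node):
                dist = ParameterDistribution.from_spec(node)
                if dist.is_stochastic:
                    yield prefix, dist
                return
            if isinstance(node, Mapping):
                for key, child in node.items():
                    yield from walk(child, f"{prefix}.{key}" if prefix else key)
        yield from walk(self.raw, "")

    def sample_draw(self, rng: np.random.Generator) -> dict[str, float]:
        """Sample one value for every stochastic parameter."""
        return {path: dist.sample(rng) for path, dist in self.distributions()}

    def scale_uncertainty(self, factor: float) -> "ScenarioConfig":
        """Return a copy with every standard error multiplied by ``factor``."""
        raw = copy.deepcopy(self.raw)

        def walk(node):
            if _is_dist_node(node):
                if node.get("se"):
                    node["se"] = float(node["se"]) * factor
                return
            if isinstance(node, Mapping):
                for child in node.values():
                    walk(child)
        walk(raw)
        return ScenarioConfig(raw=raw, life_table=self.life_table,
                              name=self.name, source=self.source)

    # -- overrides ---------------------------------------------------------
    def with_overrides(self, overrides: Mapping[str, object]) -> "ScenarioConfig":
        """Return a copy with dotted-path overrides applied.

        A path addressing a distribution node replaces its mean (the SE is
        kept); ``...se`` / ``...mean`` / ``...family`` address components
        directly.  Paths must resolve to existing parents; whole new subtrees
        (e.g. ``state_costs_control``) may be grafted at the top level.
        """
        raw = copy.deepcopy(self.raw)
        for path, value in overrides.items():
            parts = path.split(".")
            grafting = parts[0] not in raw  # new top-level subtree is allowed
            cur = raw
            for part in parts[:-1]:
                nxt = cur.get(part)
                if nxt is None:
                    if not grafting:
                        raise ConfigurationError(
                            f"override path {path!r} does not resolve")
                    cur[part] = {}
                    nxt = cur[part]
                elif not isinstance(nxt, dict):
                    raise ConfigurationError(
                        f"override path {path!r} does not resolve")
                cur = nxt
            leaf = parts[-1]
            if not grafting and leaf not in cur and not _is_dist_node(cur):
                raise ConfigurationError(
                    f"override path {path!r} does not resolve")
            existing = cur.get(leaf)
            if _is_dist_node(existing) and not isinstance(value, Mapping):
                existing = dict(existing)
                existing["mean"] = float(value)
                cur[leaf] = existing
            else:
                cur[leaf] = value
        return ScenarioConfig(raw=raw, life_table=self.life_table,
                              name=self.name, source=self.source)

    def config_hash(self) -> str:
        """Stable digest of the configuration tree, for run manifests."""
        canon = yaml.safe_dump(self.raw, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def published_base_case() -> dict:
    """Published deterministic base-case totals per scenario and strategy.

    These are the reported totals of the original evaluation this package
    re-implements (2012 euros; discounted, half-cycle-corrected).  They are
    reporting-layer inputs for validation of the incremental statistics, not
    model outputs.
    """
    path = bundled_config_path("published_base_case")
    return yaml.safe_load(path.read_text())
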