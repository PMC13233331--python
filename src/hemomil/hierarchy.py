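"""Three-level diagnostic label hierarchy.

Raw laboratory labels are grouped into detailed disease classes, which are
consolidated into 8 coarse classes used as the classification targets.
Six coarse classes are malignant (acute leukemia, MDS, MDS/MPN, MPN,
lymphoma, plasma cell neoplasm); the two non-malignant classes are
"reactive changes" and "healthy".  The order of ``coarse_classes`` is
authoritative: it fixes the index order of every probability vector
downstream, so class/index mismatches cannot occur silently.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import yaml

__all__ = ["LabelHierarchy", "HierarchyError", "load_hierarchy", "default_hierarchy"]

N_COARSE = 8
N_MALIGNANT = 6
NON_MALIGNANT = ("reactive changes", "healthy")


class HierarchyError(ValueError):
    """Raised for an invalid hierarchy configuration or an unknown label."""


@dataclass(frozen=True)
class LabelHierarchy:
    """Validated raw -> detailed -> coarse label mapping.

    Attributes
    ----------
    raw_to_detailed : mapping of raw diagnostic label to detailed class.
    detailed_to_coarse : mapping of detailed class to coarse class.
    coarse_classes : the 8 coarse class names, in authoritative order.
    malignant_flags : coarse class -> whether it is malignant.
    """

    raw_to_detailed: Mapping[str, str]
    detailed_to_coarse: Mapping[str, str]
    coarse_classes: tuple[str, ...]
    malignant_flags: Mapping[str, bool]

    def __post_init__(self) -> None:
        coarse = self.coarse_classes
        if len(coarse) != N_COARSE or len(set(coarse)) != N_COARSE:
            raise HierarchyError(
                f"expected {N_COARSE} distinct coarse classes, got {list(coarse)}"
            )
        missing = set(coarse) - set(self.malignant_flags)
        if missing:
            raise HierarchyError(f"missing malignant flag for {sorted(missing)}")
        extra = set(self.malignant_flags) - set(coarse)
        if extra:
            raise HierarchyError(f"malignant flag for unknown coarse class {sorted(extra)}")
        n_mal = sum(bool(v) for v in self.malignant_flags.values())
        if n_mal != N_MALIGNANT:
            raise HierarchyError(
                f"expected {N_MALIGNANT} malignant coarse classes, got {n_mal}"
            )
        benign = {c for c, m in self.malignant_flags.items() if not m}
        if benign != set(NON_MALIGNANT):
            raise HierarchyError(
                f"non-malignant coarse classes must be {NON_MALIGNANT}, got {sorted(benign)}"
            )
        for det, c in self.detailed_to_coarse.items():
            if c not in set(coarse):
                raise HierarchyError(
                    f"detailed class {det!r} maps to unknown coarse class {c!r}"
                )
        for raw, det in self.raw_to_detailed.items():
            if det not in self.detailed_to_coarse:
                raise HierarchyError(
                    f"raw label {raw!r} maps to dangling detailed class {det!r}"
                )

    # -- lookups -----------------------------------------------------------

    @property
    def malignant_classes(self) -> tuple[str, ...]:
        """Malignant coarse classes, in coarse-class order."""
        return tuple(c for c in self.coarse_classes if self.malignant_flags[c])

    def class_index(self, coarse: str) -> int:
        try:
            return self.coarse_classes.index(coarse)
        except ValueError:
            raise HierarchyError(f"unknown coarse class {coarse!r}") from None

    def map_label(self, raw: str) -> tuple[str, str, bool]:
        """Resolve a label through the hierarchy.

        Accepts a raw laboratory label, a detailed class name, or a coarse
        class name, and returns ``(detailed, coarse, malignant)``.  Unknown
        labels raise :class:`HierarchyError` listing the nearest known
        labels.
        """
        if raw in self.raw_to_detailed:
            detailed = self.raw_to_detailed[raw]
        elif raw in self.detailed_to_coarse:
            detailed = raw
        elif raw in self.coarse_classes:
            return raw, raw, bool(self.malignant_flags[raw])
        else:
            known = (
                list(self.raw_to_detailed)
                + list(self.detailed_to_coarse)
                + list(self.coarse_classes)
            )
            near = difflib.get_close_matches(raw, known, n=3, cutoff=0.0)
            raise HierarchyError(f"unknown label {raw!r}; nearest known labels: {near}")
        coarse = self.detailed_to_coarse[detailed]
        return detailed, coarse, bool(self.malignant_flags[coarse])


def _coerce(config: Mapping) -> LabelHierarchy:
    try:
        coarse = tuple(config["coarse_classes"])
        flags = {str(k): bool(v) for k, v in dict(config["malignant"]).items()}
        d2c = {str(k): str(v) for k, v in dict(config["detailed_to_coarse"]).items()}
        r2d = {str(k): str(v) for k, v in dict(config.get("raw_to_detailed", {})).items()}
    except KeyError as exc:
        raise HierarchyError(f"hierarchy config missing required key {exc}") from None
    return LabelHierarchy(
        raw_to_detailed=r2d,
        detailed_to_coarse=d2c,
        coarse_classes=coarse,
        malignant_flags=flags,
    )


def load_hierarchy(source: str | Path | Mapping) -> LabelHierarchy:
    """Load and validate a hierarchy from a YAML file path or a mapping.

    The file schema has four keys: ``coarse_classes`` (ordered list of 8),
    ``malignant`` (coarse class -> bool, exactly 6 true),
    ``detailed_to_coarse`` and ``raw_to_detailed`` (plain mappings).
    """
    if isinstance(source, Mapping):
        return _coerce(source)
    with open(source, "r", encoding="utf-8") as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, Mapping):
        raise HierarchyError(f"hierarchy file {source} did not parse to a mapping")
    return _coerce(config)


def default_hierarchy() -> LabelHierarchy:
    """The exemplar hierarchy shipped with the package."""
    text = resources.files("hemomil.data").joinpath("default_hierarchy.yaml").read_text()
    return _coerce(yaml.safe_load(text))
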