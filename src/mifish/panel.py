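"""Probe panel definitions for multiplex interphase FISH (miFISH).

A panel is an ordered list of locus-specific probes: gene-target probes plus
exactly two centromere reference probes (CEP3, CEP10) that act as per-nucleus
ploidy controls.  The panel order is the single source of truth for every
copy-number vector in the package: cell count rows, signal patterns, clone
genotypes and tree nodes are all indexed by it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import yaml

GENE_TARGET = "gene_target"
CENTROMERE_CONTROL = "centromere_control"
_ROLES = (GENE_TARGET, CENTROMERE_CONTROL)


class PanelError(ValueError):
    """Raised when a probe panel configuration is malformed or invalid."""


@dataclass(frozen=True)
class Probe:
    """One FISH probe: a gene target or a centromere ploidy control."""

    name: str
    role: str
    chromosome_arm: str = ""
    fluor: str = ""
    panel_id: str = "custom"

    def __post_init__(self) -> None:
        if not self.name:
            raise PanelError("probe field 'name' must be a non-empty string")
        if self.role not in _ROLES:
            raise PanelError(
                f"probe {self.name!r}: field 'role' must be one of {_ROLES}, "
                f"got {self.role!r}"
            )


@dataclass(frozen=True)
class ProbePanel:
    """Ordered, validated collection of probes.

    Invariants: probe names are unique, and exactly two probes carry the
    ``centromere_control`` role (the per-nucleus ploidy reference is the mean
    of their two signal counts).
    """

    probes: tuple[Probe, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "probes", tuple(self.probes))
        names = [p.name for p in self.probes]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise PanelError(f"duplicate probe name(s): {sorted(dupes)}")
        n_cen = sum(p.role == CENTROMERE_CONTROL for p in self.probes)
        if n_cen != 2:
            raise PanelError(
                f"a panel requires exactly two centromere_control probes, got {n_cen}"
            )

    # -- order-aware accessors -------------------------------------------------

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.probes)

    @property
    def gene_names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.probes if p.role == GENE_TARGET)

    @property
    def centromere_names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.probes if p.role == CENTROMERE_CONTROL)

    @property
    def gene_indices(self) -> tuple[int, ...]:
        return tuple(i for i, p in enumerate(self.probes) if p.role == GENE_TARGET)

    @property
    def centromere_indices(self) -> tuple[int, ...]:
        return tuple(
            i for i, p in enumerate(self.probes) if p.role == CENTROMERE_CONTROL
        )

    def __len__(self) -> int:
        return len(self.probes)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise PanelError(f"probe {name!r} is not in the panel") from None


def _default_probes() -> tuple[Probe, ...]:
    # Ten-probe panel: eight genes relevant for hepatocarcinogenesis plus the
    # CEP3/CEP10 ploidy controls.  Each fluor is used by two probes, which are
    # therefore hybridized in different panels (panel_id 1/2).
    spec = [
        ("MYC", GENE_TARGET, "8q24", "Aqua", "1"),
        ("FHIT", GENE_TARGET, "3p14", "Aqua", "2"),
        ("CCND1", GENE_TARGET, "11q13", "Green", "1"),
        ("TERT", GENE_TARGET, "5p15", "Green", "2"),
        ("TP53", GENE_TARGET, "17p13", "Gold", "1"),
        ("MET", GENE_TARGET, "7q31", "Gold", "2"),
        ("HER2", GENE_TARGET, "17q12", "Red", "1"),
        ("WWOX", GENE_TARGET, "16q23", "Red", "2"),
        ("CEP3", CENTROMERE_CONTROL, "3cen", "FarRed", "1"),
        ("CEP10", CENTROMERE_CONTROL, "10cen", "FarRed", "2"),
    ]
    return tuple(Probe(*row) for row in spec)


def default_panel() -> ProbePanel:
    """The shipped 10-probe liver-cancer panel (8 genes + CEP3/CEP10)."""
    return ProbePanel(_default_probes())


def read_panel(path: str | Path) -> ProbePanel:
    """Read a probe panel from a JSON or YAML configuration file.

    The file maps ``probes`` to a list of records with fields ``name``,
    ``role`` and optionally ``chromosome_arm``, ``fluor``, ``panel_id``.
    Probe order in the file is the panel order.
    """
    path = Path(path)
    if not path.exists():
        raise PanelError(f"panel config not found: {path}")
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:  # pragma: no cover - message passthrough
        raise PanelError(f"panel config {path} does not parse: {exc}") from exc
    if not isinstance(doc, dict) or "probes" not in doc:
        raise PanelError(f"panel config {path}: missing top-level field 'probes'")
    entries = doc["probes"]
    if not isinstance(entries, list) or not entries:
        raise PanelError(f"panel config {path}: field 'probes' must be a non-empty list")
    probes = []
    for i, entry in enumerate(entries):
        if not isinstance(entry, dict):
            raise PanelError(f"panel config {path}: probe #{i} is not a mapping")
        unknown = set(entry) - {"name", "role", "chromosome_arm", "fluor", "panel_id"}
        if unknown:
            raise PanelError(
                f"panel config {path}: probe #{i} has unknown field(s) {sorted(unknown)}"
            )
        for req in ("name", "role"):
            if req not in entry:
                raise PanelError(f"panel config {path}: probe #{i} lacks field {req!r}")
        probes.append(
            Probe(
                name=str(entry["name"]),
                role=str(entry["role"]),
                chromosome_arm=str(entry.get("chromosome_arm", "")),
                fluor=str(entry.get("fluor", "")),
                panel_id=str(entry.get("panel_id", "custom")),
            )
        )
    return ProbePanel(tuple(probes))


def write_panel(panel: ProbePanel, path: str | Path) -> None:
    """Write a panel to a JSON config round-trippable through read_panel."""
    import json

    doc = {
        "probes": [
            {
                "name": p.name,
                "role": p.role,
                "chromosome_arm": p.chromosome_arm,
                "fluor": p.fluor,
                "panel_id": p.panel_id,
            }
            for p in panel.probes
        ]
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")
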