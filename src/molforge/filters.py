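"""Lead-like triage funnel for generated hits.

Four built-in filters — property windows, structural alerts (PAINS by
default), novelty against known actives, and RAFSF synthetic feasibility —
plus a plug-in contract for external toxicity predictors. A compound's
overall verdict is the conjunction of all *enabled* filters; disabled filters
are recorded as not-evaluated (None), never as silent passes.

The numeric property windows (MW 200-600 Da, logP -1..6) and the RAFSF
cutoff (6.0) are package defaults chosen to bracket typical lead-like
chemistry; all are configuration, not constants.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

from rdkit import Chem
from rdkit.Chem import FilterCatalog

from . import chem, rafsf as rafsf_mod
from .chem import MoleculeRecord
from .errors import ConfigurationError

DEFAULT_WINDOWS: dict[str, tuple[float, float]] = {
    "mw": (200.0, 600.0),
    "logp": (-1.0, 6.0),
}

#: Toxicity plug-in contract: SMILES -> {"pass": bool, "score": float|None}.
ToxicityPlugin = Callable[[str], dict]


def null_toxicity_plugin(smiles: str) -> dict:
    """Pass-everything placeholder keeping the funnel's shape when no
    external toxicity models are wired in."""
    return {"pass": True, "score": None}


def _as_record(mol: MoleculeRecord | str) -> MoleculeRecord:
    return mol if isinstance(mol, MoleculeRecord) else MoleculeRecord.from_smiles(mol)


def property_filter(
    mol: MoleculeRecord | str,
    windows: dict[str, tuple[float, float]] | None = None,
) -> tuple[bool, list[str]]:
    """Pass iff every property lies inside its closed [min, max] window."""
    rec = _as_record(mol)
    windows = windows or DEFAULT_WINDOWS
    values = {"mw": rec.mw, "logp": rec.logp}
    violations = []
    for prop, (lo, hi) in windows.items():
        if prop not in values:
            raise ConfigurationError(f"unknown property window {prop!r}")
        v = values[prop]
        if not (lo <= v <= hi):
            violations.append(f"{prop}={v:.2f} outside [{lo:g}, {hi:g}]")
    return not violations, violations


class SmartsAlertSet:
    """A named collection of structural-alert SMARTS patterns."""

    def __init__(self, patterns: dict[str, str], name: str = "custom"):
        self.name = name
        self.patterns: dict[str, Chem.Mol] = {}
        for alert_name, smarts in patterns.items():
            query = Chem.MolFromSmarts(smarts)
            if query is None:
                raise ConfigurationError(
                    f"uncompilable SMARTS for alert {alert_name!r}: {smarts!r}"
                )
            self.patterns[alert_name] = query

    @classmethod
    def from_file(cls, path: str | Path) -> "SmartsAlertSet":
        """Read ``SMARTS<TAB>name`` lines (blank/# lines ignored)."""
        patterns = {}
        for i, line in enumerate(Path(path).read_text().splitlines()):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            smarts, _, name = line.partition("\t")
            patterns[name.strip() or f"alert{i}"] = smarts.strip()
        return cls(patterns, name=Path(path).stem)

    def matches(self, mol: Chem.Mol) -> list[str]:
        return [name for name, q in self.patterns.items() if mol.HasSubstructMatch(q)]


class PainsAlertSet:
    """The public PAINS A/B/C collection via RDKit's filter catalog."""

    name = "PAINS"

    def __init__(self):
        params = FilterCatalog.FilterCatalogParams()
        params.AddCatalog(FilterCatalog.FilterCatalogParams.FilterCatalogs.PAINS)
        self._catalog = FilterCatalog.FilterCatalog(params)

    def matches(self, mol: Chem.Mol) -> list[str]:
        return [entry.GetDescription() for entry in self._catalog.GetMatches(mol)]


def alert_filter(
    mol: MoleculeRecord | str,
    alert_set: PainsAlertSet | SmartsAlertSet | None = None,
) -> tuple[bool, list[str]]:
    """Fail iff at least one alert substructure matches; matched names listed."""
    if alert_set is None:
        alert_set = PainsAlertSet()
    rec = _as_record(mol)
    matched = alert_set.matches(rec.mol())
    return not matched, matched


def novelty_filter(
    mols: Sequence[MoleculeRecord | str], reference_actives: Iterable[str]
) -> list[bool]:
    """Per-molecule pass/fail: fail iff the canonical SMILES is a known active."""
    reference = {chem.canonicalize(s) for s in reference_actives}
    return [_as_record(m).smiles_canonical not in reference for m in mols]


@dataclass
class FilterVerdict:
    """Per-compound outcome: per-filter flags (None = not evaluated) and reasons."""

    compound_id: str
    results: dict[str, bool | None]
    reasons: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        # conjunction over evaluated filters; not-evaluated (None) is neutral
        return all(v is not False for v in self.results.values())


@dataclass
class FunnelConfig:
    """Which filters run and with what parameters."""

    enable_property: bool = True
    enable_alerts: bool = True
    enable_novelty: bool = True
    enable_feasibility: bool = True
    enable_toxicity: bool = True
    windows: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_WINDOWS)
    )
    alert_set: PainsAlertSet | SmartsAlertSet | None = None
    reference_actives: tuple[str, ...] = ()
    fragment_space: rafsf_mod.FragmentSpace | None = None
    rafsf_threshold: float = 6.0
    toxicity_plugins: tuple[ToxicityPlugin, ...] = (null_toxicity_plugin,)


def apply_funnel(
    mols: Sequence[MoleculeRecord | str], config: FunnelConfig | None = None
) -> tuple[list[FilterVerdict], list[MoleculeRecord]]:
    """Run every enabled filter over ``mols``; order-preserving verdict table.

    Returns ``(verdicts, survivors)`` where survivors are the records whose
    enabled filters all passed.
    """
    config = config or FunnelConfig()
    if config.enable_feasibility and config.fragment_space is None:
        raise ConfigurationError(
            "feasibility filter enabled but no fragment_space provided"
        )
    alert_set = config.alert_set
    if config.enable_alerts and alert_set is None:
        alert_set = PainsAlertSet()
    reference = {chem.canonicalize(s) for s in config.reference_actives}
    verdicts: list[FilterVerdict] = []
    survivors: list[MoleculeRecord] = []
    for m in mols:
        rec = _as_record(m)
        results: dict[str, bool | None] = {
            "property": None,
            "alerts": None,
            "novelty": None,
            "feasibility": None,
            "toxicity": None,
        }
        reasons: list[str] = []
        if config.enable_property:
            ok, violations = property_filter(rec, config.windows)
            results["property"] = ok
            reasons += violations
        if config.enable_alerts:
            ok, matched = alert_filter(rec, alert_set)
            results["alerts"] = ok
            reasons += [f"alert:{name}" for name in matched]
        if config.enable_novelty:
            ok = rec.smiles_canonical not in reference
            results["novelty"] = ok
            if not ok:
                reasons.append("known active")
        if config.enable_feasibility:
            result = rafsf_mod.rafsf_score(rec.mol(), config.fragment_space, rec.id)
            ok = result.score <= config.rafsf_threshold
            results["feasibility"] = ok
            if not ok:
                reasons.append(
                    f"rafsf={result.score:.2f} > {config.rafsf_threshold:g} "
                    f"(rarest: {result.rarest})"
                )
        if config.enable_toxicity:
            tox_ok = True
            for plugin in config.toxicity_plugins:
                outcome = plugin(rec.smiles_canonical)
                if not outcome.get("pass", False):
                    tox_ok = False
                    reasons.append(f"toxicity:{getattr(plugin, '__name__', 'plugin')}")
            results["toxicity"] = tox_ok
        verdict = FilterVerdict(compound_id=rec.id, results=results, reasons=reasons)
        verdicts.append(verdict)
        if verdict.passed:
            survivors.append(rec)
    return verdicts, survivors


def write_verdicts_csv(verdicts: Sequence[FilterVerdict], path: str | Path) -> None:
    filters = ["property", "alerts", "novelty", "feasibility", "toxicity"]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["compound_id", *filters, "overall", "reasons"])
        for v in verdicts:
            writer.writerow(
                [
                    v.compound_id,
                    *["" if v.results[f] is None else str(v.results[f]) for f in filters],
                    str(v.passed),
                    ";".join(v.reasons),
                ]
            )
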