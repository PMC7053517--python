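"""Marker rulebooks: explicit, ordered high/low marker rules that map a
cluster's mean z-score vector to a phenotype or functional label.

A rulebook externalises the expert-annotation step: each rule names the
markers that must be high (mean z above ``hi_threshold``) and the markers
that must be low (mean z below ``lo_threshold``).  Rules are evaluated in
priority order; the first match wins, otherwise the cluster is
``"unassigned"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .panel import PANEL

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class Rule:
    phenotype: str
    high: tuple[str, ...] = ()
    low: tuple[str, ...] = ()
    priority: int = 0
    # per-rule threshold overrides (None -> use the rulebook default)
    hi_override: float | None = None
    lo_override: float | None = None


@dataclass
class Rulebook:
    """Ordered collection of marker rules.

    Parameters
    ----------
    rules
        The rules; evaluated in ascending ``priority``.
    hi_threshold
        Mean z a "high" marker must exceed (default 0.5).
    lo_threshold
        Mean z a "low" marker must stay below (default -0.1).
    """

    rules: list[Rule] = field(default_factory=list)
    hi_threshold: float = 0.5
    lo_threshold: float = -0.1

    def __post_init__(self) -> None:
        if not self.rules:
            raise ValueError("rulebook must contain at least one rule")
        prios = [r.priority for r in self.rules]
        if len(set(prios)) != len(prios):
            raise ValueError("rule priorities must be unique")
        known = set(PANEL)
        for r in self.rules:
            unknown = (set(r.high) | set(r.low)) - known
            if unknown:
                raise ValueError(
                    f"rule {r.phenotype!r} references markers outside the "
                    f"panel: {sorted(unknown)}"
                )
        self.rules = sorted(self.rules, key=lambda r: r.priority)

    def assign(self, mean_z: dict[str, float]) -> str:
        """Label a cluster from its per-marker mean z-scores."""
        for r in self.rules:
            hi = self.hi_threshold if r.hi_override is None else r.hi_override
            lo = self.lo_threshold if r.lo_override is None else r.lo_override
            highs_ok = all(m in mean_z and mean_z[m] > hi for m in r.high)
            lows_ok = all(m in mean_z and mean_z[m] < lo for m in r.low)
            if highs_ok and lows_ok and (r.high or r.low):
                return r.phenotype
        return UNASSIGNED

    @property
    def phenotypes(self) -> list[str]:
        seen: list[str] = []
        for r in self.rules:
            if r.phenotype not in seen:
                seen.append(r.phenotype)
        return seen

    # ---- serialization -------------------------------------------------
    @classmethod
    def from_yaml(cls, path) -> "Rulebook":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        rules = [
            Rule(
                phenotype=r["phenotype"],
                high=tuple(r.get("high", ())),
                low=tuple(r.get("low", ())),
                priority=int(r.get("priority", i)),
                hi_override=r.get("hi_override"),
                lo_override=r.get("lo_override"),
            )
            for i, r in enumerate(doc["rules"])
        ]
        return cls(
            rules=rules,
            hi_threshold=float(doc.get("hi_threshold", 0.5)),
            lo_threshold=float(doc.get("lo_threshold", -0.1)),
        )

    def to_yaml(self, path) -> None:
        doc = {
            "hi_threshold": self.hi_threshold,
            "lo_threshold": self.lo_threshold,
            "rules": [
                {
                    "phenotype": r.phenotype,
                    "high": list(r.high),
                    "low": list(r.low),
                    "priority": r.priority,
                    "hi_override": r.hi_override,
                    "lo_override": r.lo_override,
                }
                for r in self.rules
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


def default_phenotype_rulebook() -> Rulebook:
    """Lineage rulebook encoding the standard melanoma-microenvironment
    marker definitions (Tcy = CD3+CD8+, Treg = CD3+CD4+FOXP3+, ...)."""
    rules = [
        Rule("Treg", high=("CD3", "CD4", "FOXP3"), priority=0),
        Rule("Tcy", high=("CD3", "CD8"), priority=1),
        # FOXP3's positive population (Treg) is small, so its z-scale is
        # compressed: "FOXP3-" here means "not elevated", not strongly
        # negative.
        Rule("Th", high=("CD3", "CD4"), low=("FOXP3",), priority=2,
             lo_override=0.2),
        Rule("Tfh", high=("CXCL13", "PD-1"), priority=3),
        Rule("BC", high=("CD20",), priority=4),
        Rule("PC", high=("IRF4", "Blimp1"), low=("CD20",), priority=5),
        Rule("Melanoma", high=("S100AB", "MelanA"), priority=6),
        Rule("Melanoma", high=("S100AB",), low=("MelanA",), priority=7),
        Rule("Melanoma", high=("MelanA",), low=("S100AB",), priority=8),
        Rule("Macroph", high=("CD68", "Lysozyme"), priority=9),
        Rule("cDC1", high=("CD141", "IRF8"), priority=10),
        Rule("cDC2", high=("CD1c", "HLA-DR"), low=("CD3", "CD20"), priority=11),
        Rule("Lang", high=("CD1a", "Langerin"), priority=12),
        Rule("pDC", high=("CD123",), priority=13),
        Rule("NK", high=("CD56",), low=("CD3",), priority=14),
        Rule("LV", high=("Podoplanin",), priority=15),
    ]
    return Rulebook(rules=rules)


def default_functional_rulebook() -> Rulebook:
    """Functional rulebook for T-cell states: active (CD69+OX40+/-),
    exhausted (TIM3 and/or LAG3 high, CD69/OX40 low/absent), transition
    (balanced), proliferating (Ki-67+) and anergic (all low)."""
    # functional markers have small positive populations, so cells not
    # expressing them sit near z = 0, not strongly negative: "low/absent"
    # in the exclusion lists means "not elevated" (override 0.3)
    rules = [
        Rule("proliferating", high=("Ki-67",), priority=0),
        Rule("transition", high=("CD69", "TIM3"), priority=1),
        Rule("active", high=("CD69",), low=("TIM3", "LAG3"), priority=2,
             lo_override=0.3),
        Rule("exhausted", high=("TIM3",), low=("CD69", "OX40"), priority=3,
             lo_override=0.3),
        Rule("exhausted", high=("LAG3",), low=("CD69", "OX40"), priority=4,
             lo_override=0.3),
        # "low or absent expression of all functional markers": a mean z
        # hovering around 0 still counts as absent, hence the laxer bound.
        Rule(
            "anergic",
            low=("CD69", "OX40", "LAG3", "TIM3", "Ki-67"),
            priority=5,
            lo_override=0.25,
        ),
    ]
    return Rulebook(rules=rules)
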