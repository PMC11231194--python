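"""Rule-based ADMET / physicochemical compound screening.

A compound passes the screen iff it fulfils every rule.  The default rule set
combines Lipinski-style drug-likeness cut-offs (MW, H-bond donors/acceptors,
logP, rotatable bonds) with predicted oral bioavailability, Caco-2
permeability, polar surface area and a hepatotoxicity veto.  Comparisons are
inclusive at the boundary; a missing property fails its rule (a criterion
cannot be fulfilled when the value is unknown).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .io import PROPERTY_FIELDS, CompoundRecord

logger = logging.getLogger("ctpflow")

_OPS = ("le", "ge", "eq")


@dataclass(frozen=True)
class ScreenRule:
    prop: str
    op: str                      # 'le' | 'ge' | 'eq'
    threshold: float | bool

    def __post_init__(self) -> None:
        if self.prop not in PROPERTY_FIELDS:
            raise ValueError(f"rule references unknown property {self.prop!r}")
        if self.op not in _OPS:
            raise ValueError(f"rule operator must be one of {_OPS}, got {self.op!r}")
        if self.op != "eq" and not (float(self.threshold) == float(self.threshold)):
            raise ValueError("rule threshold must be finite")

    def check(self, value) -> bool:
        """True iff a present value satisfies the rule (inclusive comparison)."""
        if self.op == "le":
            return value <= self.threshold
        if self.op == "ge":
            return value >= self.threshold
        return bool(value) == bool(self.threshold)

    def label(self) -> str:
        sym = {"le": "<=", "ge": ">=", "eq": "=="}[self.op]
        return f"{self.prop}{sym}{self.threshold}"


def default_rules() -> list[ScreenRule]:
    """The nine default screening rules.

    MW <= 500 Da, nHD <= 5, nHA <= 10, logP <= 5, nRot <= 10 (drug-likeness),
    OB >= 30 %, Caco-2 >= 0.4, TPSA <= 60 Å², and no predicted hepatotoxicity.
    """
    return [
        ScreenRule("mw", "le", 500),
        ScreenRule("n_hd", "le", 5),
        ScreenRule("n_ha", "le", 10),
        ScreenRule("logp", "le", 5),
        ScreenRule("n_rot", "le", 10),
        ScreenRule("ob", "ge", 30),
        ScreenRule("caco2", "ge", 0.4),
        ScreenRule("tpsa", "le", 60),
        ScreenRule("hepatotoxic", "eq", False),
    ]


@dataclass
class ScreenReport:
    """Outcome of screening a compound table.

    ``violations`` lists, for every failing compound, the violated rule labels
    (``missing:<field>`` when the property was absent).  ``per_herb`` counts
    passers per herb; a compound shared by several herbs counts once in each.
    """

    passed: list[str]
    violations: dict[str, list[str]]
    per_herb: dict[str, int]
    n_input: int
    n_shared: int
    missing_counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_pass(self) -> int:
        return len(self.passed)


def screen(compounds: list[CompoundRecord], rules: list[ScreenRule] | None = None) -> ScreenReport:
    """Apply ``rules`` (default: :func:`default_rules`) to every compound."""
    if rules is None:
        rules = default_rules()
    if not rules:
        raise ValueError("rule list is empty")
    seen_ids: set[str] = set()
    passed: list[str] = []
    violations: dict[str, list[str]] = {}
    per_herb: dict[str, int] = {}
    missing_counts: dict[str, int] = {}
    pass_records: list[CompoundRecord] = []
    for rec in compounds:
        if rec.compound_id in seen_ids:
            raise ValueError(f"duplicate compound_id {rec.compound_id!r}")
        seen_ids.add(rec.compound_id)
        viol: list[str] = []
        for rule in rules:
            v = rec.properties.get(rule.prop)
            if v is None:
                viol.append(f"missing:{rule.prop}")
                missing_counts[rule.prop] = missing_counts.get(rule.prop, 0) + 1
            elif not rule.check(v):
                viol.append(rule.label())
        if viol:
            violations[rec.compound_id] = viol
        else:
            passed.append(rec.compound_id)
            pass_records.append(rec)
    for rec in pass_records:
        for h in rec.herbs:
            per_herb[h] = per_herb.get(h, 0) + 1
    n_shared = sum(1 for rec in pass_records if len(rec.herbs) >= 2)
    if missing_counts:
        logger.info("screen: missing property counts %s", dict(sorted(missing_counts.items())))
    return ScreenReport(
        passed=passed,
        violations=violations,
        per_herb=dict(sorted(per_herb.items())),
        n_input=len(compounds),
        n_shared=n_shared,
        missing_counts=missing_counts,
    )
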