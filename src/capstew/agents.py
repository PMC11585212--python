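"""Antibiotic agent taxonomy and free-text name normalization.

Agents are identified by a canonical snake_case code and carry a
pharmacological class used by the guideline rules (e.g. ``macrolide``,
``quinolone``).  The shipped taxonomy covers the agents named by the
Norwegian CAP recommendations plus the common violators seen in practice;
unknown names degrade to class ``other`` rather than failing, so a cohort
with an exotic prescription still classifies (as non-adherent where the
rules are strict).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

import pandas as pd

AGENT_CLASSES = frozenset(
    {
        "natural_penicillin",
        "aminopenicillin",
        "macrolide",
        "aminoglycoside",
        "cephalosporin_3g",
        "penicillin_bli",
        "quinolone",
        "lincosamide",
        "tetracycline",
        "other",
    }
)


@dataclass(frozen=True)
class AntibioticAgent:
    """One antibacterial agent with its canonical code and class."""

    code: str
    display_name: str
    agent_class: str

    def __post_init__(self) -> None:
        if self.agent_class not in AGENT_CLASSES:
            raise ValueError(f"unknown agent class: {self.agent_class!r}")


def _normalize_key(name: str) -> str:
    """Lower-case and collapse separators so 'Pip-Tazo' == 'pip tazo'."""
    key = name.strip().lower()
    key = re.sub(r"[\s\-]+", " ", key)
    return key


@dataclass
class AgentTaxonomy:
    """Lookup table from free-text antibiotic names to canonical agents."""

    agents: dict[str, AntibioticAgent] = field(default_factory=dict)
    _synonyms: dict[str, str] = field(default_factory=dict)

    def add(self, agent: AntibioticAgent, synonyms: Iterable[str] = ()) -> None:
        if agent.code in self.agents:
            raise ValueError(f"duplicate agent code: {agent.code}")
        self.agents[agent.code] = agent
        for name in (agent.code, agent.display_name, *synonyms):
            self._synonyms[_normalize_key(name)] = agent.code
        # codes use '_' where display names use '/' or '-'
        self._synonyms[_normalize_key(agent.code.replace("_", " "))] = agent.code

    def get(self, code: str) -> AntibioticAgent:
        return self.agents[code]

    def __contains__(self, code: str) -> bool:
        return code in self.agents

    def codes_in_class(self, agent_class: str) -> frozenset[str]:
        return frozenset(
            code for code, a in self.agents.items() if a.agent_class == agent_class
        )

    def normalize(self, raw_name: str) -> AntibioticAgent:
        """Resolve a free-text name to a canonical agent.

        Unknown names return an agent of class ``other`` with the raw name
        preserved as the code, never an exception; an empty name is an
        input error.
        """
        if not raw_name or not raw_name.strip():
            raise ValueError("empty antibiotic name")
        key = _normalize_key(raw_name)
        code = self._synonyms.get(key)
        if code is None:
            # '/'-separated combination names are written inconsistently
            code = self._synonyms.get(_normalize_key(raw_name.replace("/", " ")))
        if code is None:
            return AntibioticAgent(
                code=raw_name.strip(), display_name=raw_name.strip(), agent_class="other"
            )
        return self.agents[code]


def load_default_taxonomy() -> AgentTaxonomy:
    """Load the packaged agent table (code, class, synonyms)."""
    with resources.files("capstew.data").joinpath("agents.csv").open() as fh:
        table = pd.read_csv(fh)
    tax = AgentTaxonomy()
    for row in table.itertuples(index=False):
        synonyms = []
        if isinstance(row.synonyms, str) and row.synonyms:
            synonyms = row.synonyms.split("|")
        tax.add(
            AntibioticAgent(
                code=row.code, display_name=row.display_name, agent_class=row.agent_class
            ),
            synonyms,
        )
    return tax


def normalize_agent(raw_name: str, taxonomy: AgentTaxonomy | None = None) -> AntibioticAgent:
    """Module-level convenience wrapper around :meth:`AgentTaxonomy.normalize`."""
    if taxonomy is None:
        taxonomy = load_default_taxonomy()
    return taxonomy.normalize(raw_name)
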