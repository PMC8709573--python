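"""Tastant panels: stimulus labels, taste-modality grouping, and series membership.

A "stimulus" here is what one recording's micropump delivered — either an
individual tastant from a five-modality series (sucrose 500 mM, denatonium
10 mM or quinine 5 mM, NaCl 1 M or 100 mM, valine or arginine 100 mM, citric
acid 100 mM) or one of the fixed compound groups (mono-/disaccharides, two
randomized bitter cocktails, four amino-acid groups, high/low salt mixes).
Every stimulus label maps to exactly one modality category; the categories are
what multimodality statistics are expressed in.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping

from .errors import UnknownTastantError

# --- individual tastants used in the two series of sequential stimulation ---
SERIES_1 = ("sucrose", "denatonium", "NaCl 1M", "valine", "citric acid")
SERIES_2 = ("sucrose", "quinine", "NaCl 100mM", "arginine", "citric acid")

_SERIES_CATEGORIES = {
    "sucrose": "sweet",
    "denatonium": "bitter",
    "quinine": "bitter",
    "NaCl 1M": "high salt",
    "NaCl 100mM": "low salt",
    "valine": "amino acid",
    "arginine": "amino acid",
    "citric acid": "sour",
}

# --- compound-group stimuli -------------------------------------------------
_GROUP_CATEGORIES = {
    "monosaccharides": "sweet",
    "disaccharides": "sweet",
    "bitter DSoTC": "bitter",
    "bitter QLSC": "bitter",
    "amino acids A": "amino acid",
    "amino acids B": "amino acid",
    "amino acids C": "amino acid",
    "amino acids D": "amino acid",
    "high salt": "high salt",
    "low salt": "low salt",
}

#: Compound membership of the group stimuli (documentation / label recovery).
GROUP_MEMBERS: Mapping[str, tuple[str, ...]] = {
    "monosaccharides": ("fructose", "glucose", "arabinose", "mannose", "galactose"),
    "disaccharides": ("sucrose", "trehalose", "maltose", "lactose", "cellobiose"),
    "bitter DSoTC": ("denatonium benzoate", "sucrose octaacetate", "theophylline", "coumarin"),
    "bitter QLSC": ("quinine", "lobeline", "strychnine", "caffeine"),
    "amino acids A": ("valine", "leucine", "isoleucine", "methionine", "tryptophan", "cysteine"),
    "amino acids B": ("alanine", "phenylalanine", "glycine", "proline", "tyrosine"),
    "amino acids C": ("arginine", "lysine", "aspartic acid", "glutamic acid", "histidine"),
    "amino acids D": ("serine", "threonine", "asparagine", "glutamine"),
    "high salt": ("NaCl 500mM", "KCl 500mM"),
    "low salt": ("NaCl 25mM", "KCl 25mM"),
}

_BITTER_STIMULI = frozenset({"denatonium", "quinine", "bitter DSoTC", "bitter QLSC"})

_ALIASES = {
    "sucrose 500 mm": "sucrose",
    "sucrose 500mm": "sucrose",
    "denatonium benzoate": "denatonium",
    "denatonium 10 mm": "denatonium",
    "quinine hemisulfate": "quinine",
    "quinine 5 mm": "quinine",
    "nacl 1 m": "NaCl 1M",
    "nacl 1000 mm": "NaCl 1M",
    "nacl 100 mm": "NaCl 100mM",
    "cia": "citric acid",
    "citric acid 100 mm": "citric acid",
    "valine 100 mm": "valine",
    "arginine 100 mm": "arginine",
    "mono": "monosaccharides",
    "monosaccharide": "monosaccharides",
    "di": "disaccharides",
    "disaccharide": "disaccharides",
    "dsotc": "bitter DSoTC",
    "qlsc": "bitter QLSC",
    "amino a": "amino acids A",
    "amino b": "amino acids B",
    "amino c": "amino acids C",
    "amino d": "amino acids D",
    "aa group a": "amino acids A",
    "aa group b": "amino acids B",
    "aa group c": "amino acids C",
    "aa group d": "amino acids D",
}


def _canon_key(label: str) -> str:
    return re.sub(r"\s+", " ", str(label).strip()).casefold()


@dataclass(frozen=True)
class TastePanel:
    """Mapping of stimulus labels to modality categories and series membership.

    Parameters
    ----------
    categories:
        stimulus label -> modality category (sweet, bitter, high salt,
        low salt, amino acid, sour).
    series:
        series name -> ordered stimulus labels presented to one animal.
    bitter:
        stimulus labels counted as bitter for the relaxed mapping-support rule.
    aliases:
        normalized alternative spellings -> canonical label.
    """

    categories: Mapping[str, str]
    series: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    bitter: frozenset = frozenset()
    aliases: Mapping[str, str] = field(default_factory=dict)

    @property
    def tastants(self) -> tuple[str, ...]:
        return tuple(self.categories)

    def __contains__(self, label: str) -> bool:
        try:
            self.normalize(label)
        except UnknownTastantError:
            return False
        return True

    def normalize(self, label: str) -> str:
        """Return the canonical stimulus label for ``label``.

        Case, surrounding whitespace and a small set of common spellings
        (e.g. "NaCl 1 M", "DSoTC") are tolerated.
        """
        if label in self.categories:
            return label
        key = _canon_key(label)
        for cand in self.categories:
            if _canon_key(cand) == key:
                return cand
        if key in self.aliases:
            return self.aliases[key]
        raise UnknownTastantError(label)

    def category(self, label: str) -> str:
        return self.categories[self.normalize(label)]

    def is_bitter(self, label: str) -> bool:
        return self.normalize(label) in self.bitter

    def series_of(self, label: str) -> str | None:
        canonical = self.normalize(label)
        for name, members in self.series.items():
            if canonical in members:
                return name
        return None


def default_panel() -> TastePanel:
    """The stimulation panel used throughout: both tastant series plus the
    compound-group stimuli, with their modality categories."""
    categories = dict(_SERIES_CATEGORIES)
    categories.update(_GROUP_CATEGORIES)
    return TastePanel(
        categories=categories,
        series={"series1": SERIES_1, "series2": SERIES_2},
        bitter=_BITTER_STIMULI,
        aliases=dict(_ALIASES),
    )
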