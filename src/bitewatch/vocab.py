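"""Drug-synonym dictionary and adverse-event term vocabulary.

FAERS drug names are free text ("BLINCYTO", "BLINATUMOMAB.",
"TARLATAMAB-DLLE" ...), so the drug dictionary maps case-insensitive
substring patterns to canonical ingredient names.  The event vocabulary
maps MedDRA-style Preferred Terms (PTs) to System Organ Classes (SOCs)
and carries the subset of PTs treated as nervous-system toxicities (NSTs).

The shipped vocabulary covers the nine FDA-approved bispecific T-cell
engagers and a minimal PT->SOC table sufficient for the NST analysis; a
full licensed MedDRA export can be substituted via the same two-column
file format (MedDRA itself cannot be redistributed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from bitewatch.model import DrugMention

#: Canonical names of the nine approved BiTEs.
BITE_DRUGS = (
    "blinatumomab",
    "elranatamab",
    "epcoritamab",
    "glofitamab",
    "mosunetuzumab",
    "talquetamab",
    "tarlatamab",
    "tebentafusp",
    "teclistamab",
)

NERVOUS_SYSTEM_SOC = "Nervous system disorders"


def _data_path(name: str) -> Path:
    return Path(str(resources.files("bitewatch").joinpath("data", name)))


@dataclass
class DrugDictionary:
    """Canonical drug name -> set of lower-cased match patterns."""

    entries: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.entries = {
            canon: {p.strip().lower() for p in pats if p.strip()}
            for canon, pats in self.entries.items()
        }

    @classmethod
    def load(cls, path: str | Path | None = None) -> "DrugDictionary":
        """Load a two-column (pattern, canonical_drug) delimited file."""
        path = Path(path) if path else _data_path("drug_synonyms.tsv")
        entries: dict[str, set[str]] = {}
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
            sep = "\t" if "\t" in header else ","
            for line in fh:
                if not line.strip():
                    continue
                pattern, canonical = line.rstrip("\n").split(sep)[:2]
                entries.setdefault(canonical.strip(), set()).add(
                    pattern.strip().lower()
                )
        return cls(entries)

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("pattern\tcanonical_drug\n")
            for canonical in sorted(self.entries):
                for pattern in sorted(self.entries[canonical]):
                    fh.write(f"{pattern}\t{canonical}\n")


@dataclass
class TermSet:
    """PT -> SOC mapping plus the NST term subset.

    Lookups are case-insensitive on trimmed strings; the stored keys are
    casefolded while ``canonical`` keeps the original spelling.
    """

    pt_to_soc: dict[str, str] = field(default_factory=dict)
    nst_terms: set[str] = field(default_factory=set)
    canonical: dict[str, str] = field(default_factory=dict)

    @classmethod
    def load(
        cls,
        pt_soc_path: str | Path | None = None,
        nst_path: str | Path | None = None,
    ) -> "TermSet":
        pt_soc_path = Path(pt_soc_path) if pt_soc_path else _data_path("pt_soc.tsv")
        nst_path = Path(nst_path) if nst_path else _data_path("nst_terms.txt")
        pt_to_soc: dict[str, str] = {}
        canonical: dict[str, str] = {}
        with open(pt_soc_path, encoding="utf-8") as fh:
            header = fh.readline()
            sep = "\t" if "\t" in header else ","
            for line in fh:
                if not line.strip():
                    continue
                pt, soc = line.rstrip("\n").split(sep)[:2]
                key = pt.strip().casefold()
                pt_to_soc[key] = soc.strip()
                canonical[key] = pt.strip()
        nst: set[str] = set()
        with open(nst_path, encoding="utf-8") as fh:
            for line in fh:
                term = line.strip()
                if term:
                    nst.add(term.casefold())
        missing = nst - set(pt_to_soc)
        if missing:
            raise ValueError(
                f"NST terms lack a PT->SOC entry: {sorted(missing)[:5]} ..."
            )
        return cls(pt_to_soc=pt_to_soc, nst_terms=nst, canonical=canonical)

    def save(self, pt_soc_path: str | Path, nst_path: str | Path) -> None:
        with open(pt_soc_path, "w", encoding="utf-8") as fh:
            fh.write("preferred_term\tsoc\n")
            for key in sorted(self.pt_to_soc):
                fh.write(f"{self.canonical.get(key, key)}\t{self.pt_to_soc[key]}\n")
        with open(nst_path, "w", encoding="utf-8") as fh:
            for key in sorted(self.nst_terms):
                fh.write(self.canonical.get(key, key) + "\n")

    @property
    def socs(self) -> set[str]:
        return set(self.pt_to_soc.values())


def match_drug(mention: DrugMention, dictionary: DrugDictionary) -> tuple[str, ...]:
    """Canonical drug(s) a mention matches, by case-insensitive substring.

    Matching runs over both the verbatim name and the active-ingredient
    field.  A mention matching patterns of two different canonical drugs
    is assigned to both (a report can legitimately list two BiTEs);
    an unmatched mention yields an empty tuple.
    """
    haystacks = [mention.verbatim_name.lower()]
    if mention.active_ingredient:
        haystacks.append(mention.active_ingredient.lower())
    hits = [
        canonical
        for canonical, patterns in dictionary.entries.items()
        if any(p in hay for p in patterns for hay in haystacks)
    ]
    return tuple(sorted(hits))


def classify_event(pt: str, terms: TermSet) -> dict:
    """Classify a PT: NST membership and SOC (``None`` when unmapped)."""
    key = pt.strip().casefold()
    return {"is_nst": key in terms.nst_terms, "soc": terms.pt_to_soc.get(key)}
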