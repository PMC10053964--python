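"""The 31-CpG / 6-gene pyrosequencing panel.

Six gene promoter amplicons (ELOVL2, EDARADD, ITGA2B, ASPA, PDE4C, FHL2)
are assayed by bisulfite pyrosequencing; each CpG within an amplicon is
addressed by its 1-based ordinal, giving canonical site ids like
``ELOVL2_CpG3``.  The default panel enumerates the 31 CpGs contained in
the six assay target sequences: ELOVL2 7, FHL2 12, PDE4C 5, ITGA2B 3,
ASPA 2, EDARADD 2.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

__all__ = [
    "PANEL_GENES",
    "PANEL_CPG_COUNTS",
    "CpGSite",
    "Panel",
    "parse_site_id",
    "default_panel",
]

PANEL_GENES = ("ASPA", "EDARADD", "ELOVL2", "FHL2", "ITGA2B", "PDE4C")

#: CpGs per gene amplicon in the pyrosequencing assay (degenerate C/G
#: positions in the sequence-to-analyze), summing to 31.
PANEL_CPG_COUNTS = {
    "ASPA": 2,
    "EDARADD": 2,
    "ELOVL2": 7,
    "FHL2": 12,
    "ITGA2B": 3,
    "PDE4C": 5,
}

# accepts "ELOVL2_CpG3" and the parenthesized "ELOVL2(CpG3)" form,
# tolerating whitespace as printed in formula listings
_SITE_RE = re.compile(
    r"^\s*(?P<gene>[A-Za-z0-9]+)\s*(?:_|\()\s*CpG\s*(?P<index>\d+)\s*\)?\s*$",
    re.IGNORECASE,
)


@dataclass(frozen=True, order=True)
class CpGSite:
    """A single CpG addressed by gene symbol and 1-based amplicon ordinal."""

    gene: str
    index: int
    chromosome: Optional[str] = field(default=None, compare=False)
    position: Optional[int] = field(default=None, compare=False)
    strand: Optional[str] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.gene not in PANEL_GENES:
            raise ValueError(
                f"unknown panel gene {self.gene!r}; expected one of {PANEL_GENES}"
            )
        if self.index < 1:
            raise ValueError(f"CpG index must be >= 1, got {self.index}")

    @property
    def site_id(self) -> str:
        return f"{self.gene}_CpG{self.index}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.site_id


def parse_site_id(text: str) -> CpGSite:
    """Parse ``GENE_CpGk`` (or the ``GENE(CpGk)`` formula notation).

    Round-trips with :attr:`CpGSite.site_id`.
    """
    m = _SITE_RE.match(text)
    if m is None:
        raise ValueError(f"cannot parse CpG site id {text!r}")
    gene = m.group("gene").upper()
    return CpGSite(gene=gene, index=int(m.group("index")))


@dataclass(frozen=True)
class Panel:
    """An ordered collection of unique CpG sites."""

    sites: tuple[CpGSite, ...]

    def __post_init__(self) -> None:
        ids = [s.site_id for s in self.sites]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate site ids in panel: {dupes}")

    @property
    def site_ids(self) -> list[str]:
        return [s.site_id for s in self.sites]

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sites:
            seen.setdefault(s.gene, None)
        return list(seen)

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self) -> Iterator[CpGSite]:
        return iter(self.sites)

    def __contains__(self, item: object) -> bool:
        if isinstance(item, CpGSite):
            return item in self.sites
        if isinstance(item, str):
            return item in set(self.site_ids)
        return False

    @classmethod
    def from_sites(cls, sites: Iterable[CpGSite]) -> "Panel":
        return cls(sites=tuple(sites))

    def to_json(self, path) -> None:
        records = [
            {
                "gene": s.gene,
                "index": s.index,
                **(
                    {"chromosome": s.chromosome, "position": s.position, "strand": s.strand}
                    if s.chromosome is not None
                    else {}
                ),
            }
            for s in self.sites
        ]
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"sites": records}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "Panel":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        sites = [
            CpGSite(
                gene=r["gene"],
                index=int(r["index"]),
                chromosome=r.get("chromosome"),
                position=r.get("position"),
                strand=r.get("strand"),
            )
            for r in payload["sites"]
        ]
        return cls.from_sites(sites)


def default_panel() -> Panel:
    """The built-in 31-site panel spanning the six assay amplicons."""
    sites = [
        CpGSite(gene, k)
        for gene in PANEL_GENES
        for k in range(1, PANEL_CPG_COUNTS[gene] + 1)
    ]
    return Panel.from_sites(sites)
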