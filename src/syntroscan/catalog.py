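"""Gene-family category catalogs.

A catalog assigns gene-family identifiers (COG or KO tokens) to named
categories in two divisions:

* ``universal`` — housekeeping families (ribosome, translation,
  transcription, replication) expected at similar normalized abundance in
  every community; the negative-control feature set.
* ``syntroph`` — families of energy-transfer genes (hydrogenases, formate
  dehydrogenases, FeS oxidoreductases, Rnf/Fnr, Fix) drawn from sequenced
  syntroph genomes; the predictive feature set.

Catalogs are plain three-column delimited text (``division  category
family_id``), tab by default with comma accepted, header required, ``#``
comments ignored. Family identifiers are opaque tokens; they are never
validated against live COG/KO databases, whose contents drift between
releases.
"""

from __future__ import annotations

import csv
import io
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

DIVISIONS = ("universal", "syntroph")

#: Table-style display labels accepted for divisions in catalog files.
_DIVISION_ALIASES = {
    "universal": "universal",
    "universally present": "universal",
    "syntroph": "syntroph",
    "syntroph associated": "syntroph",
    "syntroph-associated": "syntroph",
}


class CatalogError(ValueError):
    """Malformed or unusable catalog input."""


def dedupe_category(members: Iterable[str]) -> list[str]:
    """Remove repeated family identifiers, keeping first-appearance order.

    A family listed twice under the same category is counted once; the same
    family may still legitimately appear in two *different* categories.
    """
    seen: set[str] = set()
    out: list[str] = []
    for m in members:
        if m not in seen:
            seen.add(m)
            out.append(m)
    return out


def _validate_family_id(token: str) -> str:
    token = token.strip()
    if not token:
        raise CatalogError("empty family identifier")
    if any(c.isspace() for c in token):
        raise CatalogError(f"family identifier contains whitespace: {token!r}")
    return token


@dataclass(frozen=True)
class Category:
    """A named set of gene families within one division."""

    name: str
    division: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.division not in DIVISIONS:
            raise CatalogError(f"unknown division: {self.division!r}")
        if not self.members:
            raise CatalogError(f"category {self.name!r} has no members")
        if len(set(self.members)) != len(self.members):
            raise CatalogError(f"category {self.name!r} has duplicate members")

    @property
    def member_set(self) -> frozenset[str]:
        return frozenset(self.members)

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class Catalog:
    """Ordered collection of categories in one gene-family namespace."""

    namespace: str = "COG"
    categories: list[Category] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [c.name for c in self.categories]
        if len(set(names)) != len(names):
            raise CatalogError("duplicate category names in catalog")

    def __iter__(self):
        return iter(self.categories)

    def __len__(self) -> int:
        return len(self.categories)

    def __getitem__(self, name: str) -> Category:
        for c in self.categories:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def category_names(self) -> list[str]:
        return [c.name for c in self.categories]

    @property
    def divisions(self) -> dict[str, str]:
        return {c.name: c.division for c in self.categories}

    def subset(self, division: str) -> "Catalog":
        """Catalog restricted to one division, preserving order."""
        if division not in DIVISIONS:
            raise CatalogError(f"unknown division: {division!r}")
        return Catalog(
            namespace=self.namespace,
            categories=[c for c in self.categories if c.division == division],
        )

    def validate_for_pipeline(self) -> None:
        """Require at least one category in each division."""
        divs = {c.division for c in self.categories}
        missing = set(DIVISIONS) - divs
        if missing:
            raise CatalogError(
                "catalog must contain at least one category in each division; "
                f"missing: {', '.join(sorted(missing))}"
            )


def _parse_catalog_rows(rows: Iterable[Sequence[str]], namespace: str,
                        source: str) -> Catalog:
    order: list[str] = []
    division_of: dict[str, str] = {}
    members: dict[str, list[str]] = {}
    n_dropped = 0
    for lineno, row in rows:
        if len(row) != 3:
            raise CatalogError(
                f"{source}:{lineno}: expected 3 columns "
                f"(division, category, family_id), got {len(row)}"
            )
        div_raw, cat, fam = (x.strip() for x in row)
        div = _DIVISION_ALIASES.get(div_raw.lower())
        if div is None:
            raise CatalogError(f"{source}:{lineno}: unknown division token {div_raw!r}")
        if not cat:
            raise CatalogError(f"{source}:{lineno}: empty category name")
        fam = _validate_family_id(fam)
        if cat not in division_of:
            order.append(cat)
            division_of[cat] = div
            members[cat] = []
        elif division_of[cat] != div:
            raise CatalogError(
                f"{source}:{lineno}: category {cat!r} assigned to both divisions"
            )
        if fam in members[cat]:
            n_dropped += 1
        else:
            members[cat].append(fam)
    if not order:
        raise CatalogError("empty catalog")
    if n_dropped:
        logger.info("removed %d duplicate member(s) within categories", n_dropped)
    cats = [Category(name, division_of[name], tuple(members[name])) for name in order]
    return Catalog(namespace=namespace, categories=cats)


def _read_delimited(text: str, source: str):
    lines = [
        (i + 1, ln) for i, ln in enumerate(text.splitlines())
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not lines:
        raise CatalogError("empty catalog")
    delimiter = "\t" if "\t" in lines[0][1] else ","
    header_no, header = lines[0]
    cols = [c.strip().lower() for c in next(csv.reader([header], delimiter=delimiter))]
    if cols[:3] != ["division", "category", "family_id"]:
        raise CatalogError(
            f"{source}:{header_no}: expected header 'division category family_id', "
            f"got {cols!r}"
        )
    for lineno, ln in lines[1:]:
        yield lineno, next(csv.reader([ln], delimiter=delimiter))


def load_catalog(path: str | Path, namespace: str = "COG") -> Catalog:
    """Load a catalog from three-column delimited text.

    Within-category duplicate families are removed (and logged); file order
    of first appearance is preserved for categories and members.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"catalog file not found: {path}")
    text = path.read_text(encoding="utf-8")
    return _parse_catalog_rows(_read_delimited(text, str(path)), namespace, str(path))


def loads_catalog(text: str, namespace: str = "COG") -> Catalog:
    """Parse a catalog from an in-memory string (same format as files)."""
    return _parse_catalog_rows(_read_delimited(text, "<string>"), namespace, "<string>")


def write_catalog(catalog: Catalog, path: str | Path) -> None:
    """Write a catalog as tab-delimited text; round-trips with load_catalog."""
    buf = io.StringIO()
    buf.write("division\tcategory\tfamily_id\n")
    for cat in catalog.categories:
        for fam in cat.members:
            buf.write(f"{cat.division}\t{cat.name}\t{fam}\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def _ko_token(cog_id: str) -> str:
    # deterministic placeholder mapping COGxxxx -> Kxxxxx for the example
    # KO-namespace catalog; preserves structure, not real KO assignments
    digits = "".join(c for c in cog_id if c.isdigit()) or "0"
    return f"K{int(digits) % 100000:05d}"


def example_catalog(namespace: str = "COG") -> Catalog:
    """The bundled example catalog (synthetic, representative identifiers).

    The 13 category names and the universal/syntroph split follow the
    published search scheme, but the member lists are *placeholders*:
    plausible identifiers standing in for curated per-category gene-family
    lists. Substitute a curated catalog file for real analyses.
    """
    text = (
        resources.files("syntroscan.data")
        .joinpath("example_catalog_cog.tsv")
        .read_text(encoding="utf-8")
    )
    cat = loads_catalog(text, namespace="COG")
    if namespace.upper() == "COG":
        return cat
    if namespace.upper() == "KO":
        return Catalog(
            namespace="KO",
            categories=[
                Category(c.name, c.division, tuple(_ko_token(m) for m in c.members))
                for c in cat.categories
            ],
        )
    raise CatalogError(f"unknown namespace: {namespace!r}")
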