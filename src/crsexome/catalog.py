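"""Candidate-gene catalog: union of flat source lists with OMIM models.

Sources are tab-separated files (``symbol [models] [synonyms]``); entries
are de-duplicated through a synonym map and queried case-insensitively.
No live HPO / PanelApp / OMIM queries are performed — the catalog is built
entirely from user-supplied files so runs are reproducible offline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

VALID_MODELS = frozenset({"AD", "AR", "XLD", "XLR"})


class CatalogParseError(ValueError):
    pass


@dataclass
class GeneCatalogEntry:
    symbol: str
    sources: set[str] = field(default_factory=set)
    omim_models: set[str] = field(default_factory=set)
    synonyms: set[str] = field(default_factory=set)


class GeneCatalog:
    """Synonym-aware candidate-gene catalog."""

    def __init__(self) -> None:
        self._entries: dict[str, GeneCatalogEntry] = {}
        self._index: dict[str, str] = {}  # normalized symbol/synonym -> canonical

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, symbol: str) -> bool:
        return self.lookup(symbol) is not None

    def entries(self) -> list[GeneCatalogEntry]:
        return [self._entries[s] for s in sorted(self._entries)]

    def add(self, symbol: str, source: str, models: Iterable[str] = (),
            synonyms: Iterable[str] = ()) -> GeneCatalogEntry:
        symbol = symbol.strip().upper()
        models = {m.strip().upper() for m in models if m.strip()}
        bad = models - VALID_MODELS
        if bad:
            raise CatalogParseError(f"unknown inheritance model(s) {sorted(bad)} "
                                    f"for gene {symbol}")
        canonical = self._index.get(symbol, symbol)
        entry = self._entries.setdefault(canonical, GeneCatalogEntry(canonical))
        entry.sources.add(source)
        entry.omim_models |= models
        self._index[symbol] = canonical
        for syn in synonyms:
            syn = syn.strip().upper()
            if syn and syn != canonical:
                entry.synonyms.add(syn)
                self._index[syn] = canonical
        return entry

    def lookup(self, symbol: str) -> GeneCatalogEntry | None:
        """Exact, case-insensitive, synonym-aware lookup (no fuzzy matching)."""
        canonical = self._index.get(str(symbol).strip().upper())
        return self._entries.get(canonical) if canonical else None


def _parse_source_file(path: Path) -> list[tuple[str, list[str], list[str]]]:
    rows = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if fields[0].strip().lower() == "symbol":  # header
            continue
        symbol = fields[0].strip()
        if not symbol:
            raise CatalogParseError(f"{path}:{lineno}: empty gene symbol")
        models = [m for m in fields[1].split(",")] if len(fields) > 1 else []
        synonyms = [s for s in fields[2].split(",")] if len(fields) > 2 else []
        rows.append((symbol, models, synonyms))
    return rows


def build_catalog(source_files: Mapping[str, str | Path]) -> GeneCatalog:
    """Union the source files into one catalog.

    ``source_files`` maps a source tag (e.g. ``literature``,
    ``hpo_craniosynostosis``) to a TSV path. The result is independent of
    the order in which sources are supplied.
    """
    catalog = GeneCatalog()
    for source in sorted(source_files):
        path = Path(source_files[source])
        for symbol, models, synonyms in _parse_source_file(path):
            try:
                catalog.add(symbol, source, models, synonyms)
            except CatalogParseError as exc:
                raise CatalogParseError(f"{path}: {exc}") from exc
    return catalog


def write_source_files(out_dir: str | Path,
                       sources: Mapping[str, list[tuple[str, str, str]]]) -> dict[str, Path]:
    """Write catalog source TSVs and return {source: path}."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for source in sorted(sources):
        path = out_dir / f"{source}.tsv"
        lines = ["symbol\tmodels\tsynonyms"]
        for symbol, models, synonyms in sources[source]:
            lines.append(f"{symbol}\t{models}\t{synonyms}")
        path.write_text("\n".join(lines) + "\n")
        paths[source] = path
    return paths
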