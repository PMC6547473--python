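"""Reference catalogs and the local reference registry.

A registry is a TSV file mapping reference names to local paths::

    <name> <TAB> <fasta path> <TAB> <annotation path or "-">

Catalog names (``igc``, ``om-rgc``, ...) and host-genome names (``hg19``,
``mm10``, ...) are plain registry keys; host genomes are simply catalogs
without an annotation table.  Relative paths are resolved against the
registry file's directory.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .errors import RegistryError
from .seqio import read_fasta


@dataclass
class ReferenceCatalog:
    """A named reference: FASTA sequences plus an optional gene→feature table."""

    name: str
    fasta_path: Path
    annotation_path: Path | None = None
    _sequences: dict | None = None

    @property
    def sequences(self) -> dict[str, str]:
        if self._sequences is None:
            self._sequences = read_fasta(self.fasta_path)
            if len(set(self._sequences)) != len(self._sequences):  # pragma: no cover
                raise RegistryError(f"duplicate sequence names in {self.fasta_path}")
        return self._sequences

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    @property
    def names(self) -> list[str]:
        return list(self.sequences)


class Registry:
    """Name → ReferenceCatalog resolution backed by a registry TSV file."""

    def __init__(self, entries: dict[str, ReferenceCatalog], path: Path | None = None):
        self.entries = entries
        self.path = path

    @classmethod
    def load(cls, path: str | Path) -> "Registry":
        path = Path(path)
        if not path.is_file():
            raise RegistryError(f"registry file not found: {path}")
        base = path.parent
        entries: dict[str, ReferenceCatalog] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise RegistryError(
                        f"{path}:{lineno}: expected 3 tab-separated fields, got {len(parts)}")
                name, fasta, ann = parts
                if name in entries:
                    raise RegistryError(f"{path}:{lineno}: duplicate reference name {name!r}")
                fasta_p = (base / fasta) if not Path(fasta).is_absolute() else Path(fasta)
                ann_p = None
                if ann != "-":
                    ann_p = (base / ann) if not Path(ann).is_absolute() else Path(ann)
                entries[name] = ReferenceCatalog(name, fasta_p, ann_p)
        return cls(entries, path)

    def resolve(self, name: str) -> ReferenceCatalog:
        if name not in self.entries:
            known = ", ".join(sorted(self.entries)) or "none"
            raise RegistryError(f"unknown reference {name!r} (registry has: {known})")
        cat = self.entries[name]
        if not cat.fasta_path.is_file():
            raise RegistryError(f"reference {name!r}: FASTA not found at {cat.fasta_path}")
        return cat

    def probe(self, name: str) -> str | None:
        """Pre-flight check of one reference; returns a finding or None."""
        if name not in self.entries:
            known = ", ".join(sorted(self.entries)) or "none"
            return f"unknown reference {name!r} (registry has: {known})"
        cat = self.entries[name]
        if not cat.fasta_path.is_file():
            return f"reference {name!r}: FASTA not found at {cat.fasta_path}"
        if cat.annotation_path is not None and not cat.annotation_path.is_file():
            return f"reference {name!r}: annotation table not found at {cat.annotation_path}"
        return None


def write_registry(entries: dict[str, tuple[str | Path, str | Path | None]],
                   path: str | Path) -> Path:
    """Write a registry TSV; values are (fasta_path, annotation_path_or_None)."""
    path = Path(path)
    with open(path, "w") as fh:
        for name in sorted(entries):
            fasta, ann = entries[name]
            fh.write(f"{name}\t{fasta}\t{ann if ann is not None else '-'}\n")
    return path
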