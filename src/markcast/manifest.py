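"""Dataset manifests: the context metadata attached to each peak file.

A "context" is the point in (tissue, developmental stage, species) space a
histone-mark dataset was collected in; the manifest is the table mapping
``dataset_id`` to that point plus the assayed mark.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .errors import ConfigurationError

MARKS = ("H3K4me1", "H3K27ac")

MANIFEST_COLUMNS = ("dataset_id", "tissue", "stage_coord", "species", "mark", "path")


@dataclass(frozen=True)
class ContextMeta:
    """Metadata for one peak dataset: the axes of its cellular context."""

    dataset_id: str
    tissue: str
    stage_coord: float
    species: str
    mark: str
    path: str | None = None

    def __post_init__(self) -> None:
        if self.mark not in MARKS:
            raise ConfigurationError(
                f"unknown mark {self.mark!r}; expected one of {MARKS}"
            )


def check_manifest(manifest: list[ContextMeta]) -> None:
    ids = [m.dataset_id for m in manifest]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ConfigurationError(f"duplicate dataset_id(s) in manifest: {dupes}")


def write_manifest(manifest: list[ContextMeta], path) -> None:
    check_manifest(manifest)
    with open(path, "w") as fh:
        fh.write("\t".join(MANIFEST_COLUMNS) + "\n")
        for m in manifest:
            fh.write(
                f"{m.dataset_id}\t{m.tissue}\t{m.stage_coord!r}\t"
                f"{m.species}\t{m.mark}\t{m.path or ''}\n"
            )


def read_manifest(path) -> list[ContextMeta]:
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ConfigurationError(f"empty manifest {path}")
    header = tuple(lines[0].split("\t"))
    if header != MANIFEST_COLUMNS:
        raise ConfigurationError(
            f"manifest header {header} != expected {MANIFEST_COLUMNS}"
        )
    out = []
    for line in lines[1:]:
        if not line.strip():
            continue
        did, tissue, stage, species, mark, p = line.split("\t")
        out.append(
            ContextMeta(did, tissue, float(stage), species, mark, path=p or None)
        )
    check_manifest(out)
    return out
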