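"""AAindex1 flat-file parsing and the bundled accessible-surface-area index.

AAindex1 records are ``//``-delimited blocks; the 20 numeric values sit on
the two lines following the ``I`` header, whose column labels pair the
amino acids row-wise (``A/L  R/K ...`` means the first data line carries
A R N D C Q E G H I and the second L K M F P S T W Y V).  Values given as
``NA`` are replaced by 0, the convention used when screening indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .alphabet import AMINO_ACIDS


@dataclass(frozen=True)
class PropertyIndex:
    """A 20-value amino-acid property index (AAindex entry or user-supplied)."""

    name: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        missing = set(AMINO_ACIDS) - set(self.values)
        if missing:
            raise ValueError(f"index {self.name!r} missing amino acids: {sorted(missing)}")
        extra = set(self.values) - set(AMINO_ACIDS)
        if extra:
            raise ValueError(f"index {self.name!r} has non-standard keys: {sorted(extra)}")


def parse_aaindex(text: str) -> list[PropertyIndex]:
    """Parse every record of an AAindex1 flat file.

    Unparseable records raise ``ValueError`` naming the accession; use
    :func:`parse_aaindex_lenient` to skip them instead.
    """
    indices = []
    for block in text.split("//"):
        block = block.strip()
        if not block:
            continue
        indices.append(_parse_record(block))
    if not indices:
        raise ValueError("no AAindex records found")
    return indices


def parse_aaindex_lenient(text: str) -> tuple[list[PropertyIndex], list[str]]:
    """Parse records, skipping broken ones; returns (indices, warning strings)."""
    indices, warnings = [], []
    for block in text.split("//"):
        block = block.strip()
        if not block:
            continue
        try:
            indices.append(_parse_record(block))
        except ValueError as exc:
            warnings.append(str(exc))
    return indices, warnings


def _parse_record(block: str) -> PropertyIndex:
    lines = block.splitlines()
    name = "?"
    for line in lines:
        if line.startswith("H "):
            name = line[2:].strip()
            break
    i_row = next((k for k, line in enumerate(lines) if line.startswith("I ")), None)
    if i_row is None or i_row + 2 > len(lines) - 1:
        raise ValueError(f"record {name!r}: missing 'I' header or data lines")
    pairs = lines[i_row][1:].split()
    firsts = [p.split("/")[0] for p in pairs]
    seconds = [p.split("/")[1] for p in pairs]
    row1 = _parse_values(lines[i_row + 1], name)
    row2 = _parse_values(lines[i_row + 2], name)
    if len(row1) != len(firsts) or len(row2) != len(seconds):
        raise ValueError(f"record {name!r}: value count does not match 'I' header")
    values = dict(zip(firsts, row1)) | dict(zip(seconds, row2))
    return PropertyIndex(name=name, values=values)


def _parse_values(line: str, name: str) -> list[float]:
    out = []
    for tok in line.split():
        if tok.upper() == "NA":
            out.append(0.0)  # AAindex 'NA' convention
        else:
            try:
                out.append(float(tok))
            except ValueError:
                raise ValueError(f"record {name!r}: bad value {tok!r}") from None
    return out


def load_aaindex_file(path: str | Path) -> list[PropertyIndex]:
    return parse_aaindex(Path(path).read_text())


def janin_asa_index() -> PropertyIndex:
    """The bundled Janin average-accessible-surface-area index (Å² units)."""
    text = resources.files("acetylsite.data").joinpath("janin_asa.aaindex").read_text()
    return parse_aaindex(text)[0]
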