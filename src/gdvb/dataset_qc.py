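"""Entry-level inclusion filters for building a training/evaluation set.

The rules mirror the screening applied to a non-redundant X-ray set before
model fitting: assemblies with more than 10 000 atoms, missing B values,
any B value above 200 Å², a near-constant B column (sd below 0.1 Å²) or
poor backbone/side-chain geometry (Ramachandran or rotamer Z-score below
-2) are excluded.  Sequence-culling-style criteria (resolution window,
R value, chain length) are optional rules evaluated on the supplied
metadata only; sequence identity itself cannot be computed here.

Boundary semantics follow the printed wording literally: "more than",
"greater than", "below" and "less than" are all strict, so e.g. an entry
with b_max exactly 200 Å² passes that rule.  Whether the 200 Å² bound
refers to any atom or to the maximum is read as any atom, which is
equivalent to testing the maximum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields
from pathlib import Path

import pandas as pd

__all__ = ["EntryMetadata", "QCThresholds", "QCReport", "apply_filters", "batch_qc"]


@dataclass
class EntryMetadata:
    entry_id: str
    n_atoms: int | None = None
    b_min: float | None = None
    b_max: float | None = None
    b_sd: float | None = None
    has_missing_b: bool | None = None
    resolution: float | None = None
    r_value: float | None = None
    ramachandran_z: float | None = None
    rotamer_z: float | None = None
    n_residues: int | None = None


@dataclass
class QCThresholds:
    max_atoms: int = 10_000
    max_b: float = 200.0  # Å²
    min_b_sd: float = 0.1  # Å²
    min_ramachandran_z: float = -2.0
    min_rotamer_z: float = -2.0
    resolution_min: float = 1.6  # Å
    resolution_max: float = 2.6  # Å
    max_r_value: float = 0.25
    min_residues: int = 50
    max_residues: int = 500

    def write(self, path: str | Path) -> None:
        lines = [f"{f.name}={getattr(self, f.name)!r}" for f in fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "QCThresholds":
        kv = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            kv[key.strip()] = val.strip()
        kwargs = {}
        for f in fields(cls):
            if f.name in kv:
                kwargs[f.name] = type(getattr(cls(), f.name))(float(kv[f.name]))
        return cls(**kwargs)


@dataclass
class QCReport:
    entry_id: str
    failures: list[tuple[str, object]]  # (rule id, observed value)

    @property
    def passed(self) -> bool:
        return not self.failures


def apply_filters(meta: EntryMetadata, thresholds: QCThresholds | None = None) -> QCReport:
    """Evaluate every inclusion rule independently; list each violation.

    Rules whose metadata field is absent (None) are skipped with a warning;
    QC never raises on values.
    """
    th = thresholds or QCThresholds()
    failures: list[tuple[str, object]] = []
    skipped: list[str] = []

    def rule(rule_id: str, value, bad: bool) -> None:
        if value is None:
            skipped.append(rule_id)
        elif bad:
            failures.append((rule_id, value))

    m = meta
    rule("max_atoms", m.n_atoms, m.n_atoms is not None and m.n_atoms > th.max_atoms)
    rule("missing_b", m.has_missing_b, bool(m.has_missing_b))
    rule("max_b", m.b_max, m.b_max is not None and m.b_max > th.max_b)
    rule("min_b_sd", m.b_sd, m.b_sd is not None and m.b_sd < th.min_b_sd)
    rule(
        "ramachandran_z",
        m.ramachandran_z,
        m.ramachandran_z is not None and m.ramachandran_z < th.min_ramachandran_z,
    )
    rule(
        "rotamer_z",
        m.rotamer_z,
        m.rotamer_z is not None and m.rotamer_z < th.min_rotamer_z,
    )
    rule(
        "resolution_range",
        m.resolution,
        m.resolution is not None
        and not (th.resolution_min <= m.resolution <= th.resolution_max),
    )
    rule("max_r_value", m.r_value, m.r_value is not None and m.r_value > th.max_r_value)
    rule(
        "residue_range",
        m.n_residues,
        m.n_residues is not None
        and not (th.min_residues <= m.n_residues <= th.max_residues),
    )
    if skipped:
        warnings.warn(
            f"{meta.entry_id}: rules skipped for missing metadata: {skipped}",
            stacklevel=2,
        )
    return QCReport(entry_id=meta.entry_id, failures=failures)


def batch_qc(table: pd.DataFrame, thresholds: QCThresholds | None = None) -> pd.DataFrame:
    """Run :func:`apply_filters` on a TSV-style metadata table.

    Expects one row per entry with :class:`EntryMetadata` field names as
    columns (missing columns are treated as absent metadata); returns a
    table with ``entry_id``, ``passed`` and a semicolon-joined ``failures``
    column.
    """
    field_names = {f.name for f in fields(EntryMetadata)}
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _, row in table.iterrows():
            kwargs = {
                k: (None if pd.isna(v) else v)
                for k, v in row.items()
                if k in field_names
            }
            if kwargs.get("n_atoms") is not None:
                kwargs["n_atoms"] = int(kwargs["n_atoms"])
            if kwargs.get("n_residues") is not None:
                kwargs["n_residues"] = int(kwargs["n_residues"])
            rep = apply_filters(EntryMetadata(**kwargs), thresholds)
            rows.append(
                {
                    "entry_id": rep.entry_id,
                    "passed": rep.passed,
                    "failures": ";".join(
                        f"{rid}={val}" for rid, val in rep.failures
                    ),
                }
            )
    return pd.DataFrame(rows)
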