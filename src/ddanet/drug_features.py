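"""Binary substructure fingerprints of drugs from SMILES strings.

Each drug is featurised as a fixed-length 0/1 vector: bit k is set iff the
molecule contains substructure key k. The default key collection is the
public 166-key MACCS dictionary; a user-supplied SMARTS list may be used
instead. No folding or hashing is applied — every bit is an explicit
substructure match.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import MACCSkeys

from .exceptions import ConfigError, ParseError

RDLogger.DisableLog("rdApp.*")  # rdkit parse chatter; errors are raised explicitly


@dataclass(frozen=True)
class SmilesRecord:
    drug_id: str
    smiles: str


class SubstructureKeySet:
    """A named collection of substructure keys.

    ``name="maccs"`` uses the 166 public MACCS keys (rdkit's bit 0 is unused
    and dropped). Alternatively pass an explicit list of SMARTS patterns.
    """

    def __init__(self, name: str = "maccs", smarts: Sequence[str] | None = None):
        self.name = name
        if smarts is not None:
            self._patterns = []
            for s in smarts:
                patt = Chem.MolFromSmarts(s)
                if patt is None:
                    raise ConfigError(f"invalid SMARTS pattern {s!r}")
                self._patterns.append(patt)
            self.n_keys = len(self._patterns)
        elif name == "maccs":
            self._patterns = None
            self.n_keys = 166
        else:
            raise ConfigError(f"unknown keyset {name!r} and no SMARTS list given")

    def bits(self, mol: Chem.Mol) -> np.ndarray:
        if self._patterns is None:
            fp = MACCSkeys.GenMACCSKeys(mol)  # 167 bits, bit 0 always unset
            return np.array([fp.GetBit(i) for i in range(1, 167)], dtype=np.uint8)
        return np.array(
            [mol.HasSubstructMatch(p) for p in self._patterns], dtype=np.uint8
        )


MACCS_KEYSET = SubstructureKeySet("maccs")


def fingerprint(record: SmilesRecord, keyset: SubstructureKeySet = MACCS_KEYSET) -> np.ndarray:
    """Binary substructure vector of one drug; unparsable SMILES is an error."""
    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:
        raise ParseError(f"drug {record.drug_id!r}: unparsable SMILES {record.smiles!r}")
    return keyset.bits(mol)


@dataclass(frozen=True)
class DrugAttributeMatrix:
    """Row-per-drug binary attribute matrix R_a."""

    ids: tuple[str, ...]
    values: np.ndarray  # (n_drugs, n_keys), uint8

    def row(self, drug: str) -> np.ndarray:
        return self.values[self.ids.index(drug)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids))

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")


def build_attribute_matrix(
    records: Sequence[SmilesRecord],
    keyset: SubstructureKeySet = MACCS_KEYSET,
    on_parse_error: str = "drop",
) -> DrugAttributeMatrix:
    """Fingerprint a list of drugs into the attribute matrix R_a.

    Row order follows input order. ``on_parse_error`` is ``"drop"`` (default:
    skip the drug with a warning, excluding it from downstream use) or
    ``"raise"``.
    """
    if not records:
        raise ConfigError("no SMILES records given")
    ids = [r.drug_id for r in records]
    if len(set(ids)) != len(ids):
        raise ConfigError("duplicate drug ids in SMILES records")
    if on_parse_error not in ("drop", "raise"):
        raise ConfigError(f"unknown parse-error policy {on_parse_error!r}")
    kept, rows = [], []
    for rec in records:
        try:
            rows.append(fingerprint(rec, keyset))
        except ParseError:
            if on_parse_error == "raise":
                raise
            warnings.warn(f"dropping drug {rec.drug_id!r}: unparsable SMILES", stacklevel=2)
            continue
        kept.append(rec.drug_id)
    if not kept:
        raise ConfigError("no drug had a parsable SMILES")
    return DrugAttributeMatrix(tuple(kept), np.vstack(rows))


def load_smiles_table(path: str | Path, delimiter: str = "\t") -> list[SmilesRecord]:
    """Read a 2-column table (drug id, SMILES) into records."""
    records = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split(delimiter)
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 fields")
            records.append(SmilesRecord(fields[0], fields[1]))
    return records
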