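"""Training-set augmentation with SMILES spellings and tautomers.

A molecule has many valid SMILES spellings; training on several of them acts
as data augmentation for graph networks whose featurization is sensitive to
the written form (kekulized vs aromatic rings, explicit hydrogens, dative
bonds).  Each curated training chemical is expanded into a deduplicated set
of variants that all carry the parent's log Sw label:

* ``canonical`` / ``aromatic`` — the toolkit canonical form (aromatic labels),
* ``universal`` — the structure written in InChI auxiliary atom order,
* ``inchified`` — the canonical form of the InChI round-tripped structure,
* ``kekulized`` — alternating single/double ring bonds,
* ``explicit_h`` — every hydrogen count written in brackets,
* ``dative`` — charge-separated motifs (e.g. nitro) rewritten with dative
  bonds where the toolkit admits one,
* ``tautomer`` — rule-based tautomer enumeration, randomly capped at 50 per
  parent to avoid over-weighting tautomer-rich chemicals.

Every non-tautomer variant must round-trip to the parent's full InChIKey;
tautomers must match the parent's molecular formula and the 14-character
InChIKey skeleton.  Variants failing validation are dropped and logged.
Validation and test sets are never augmented.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import inchi, rdMolDescriptors
from rdkit.Chem.MolStandardize import rdMolStandardize

from .curation import CuratedDataset, CuratedRecord
from .records import StandardizedMolecule, mol_from_smiles, standardize_structure


class VariantKind(str, Enum):
    canonical = "canonical"
    universal = "universal"
    inchified = "inchified"
    kekulized = "kekulized"
    aromatic = "aromatic"
    explicit_h = "explicit_h"
    dative = "dative"
    tautomer = "tautomer"


@dataclass(frozen=True)
class AugmentedExample:
    variant_smiles: str
    parent_id: str  # parent InChIKey
    label: float
    variant_kind: VariantKind


@dataclass
class AugmentationConfig:
    tautomer_cap: int = 50
    max_raw_tautomers: int = 512  # hard enumerator limit before the random cap
    include_kinds: frozenset[VariantKind] = frozenset(VariantKind)


@dataclass
class AugmentationLog:
    skipped: list[tuple[str, str, str]] = field(default_factory=list)  # (parent, kind, why)
    per_kind_counts: dict[str, int] = field(default_factory=dict)
    cross_parent_collisions: list[tuple[str, str, str]] = field(default_factory=list)

    def skip(self, parent: str, kind: str, why: str) -> None:
        self.skipped.append((parent, kind, why))


def _inchikey(mol: Chem.Mol) -> str:
    return inchi.MolToInchiKey(mol) or ""


def _universal_smiles(mol: Chem.Mol) -> str | None:
    """Write the molecule in InChI auxiliary-info atom order, non-canonically."""
    result = inchi.MolToInchiAndAuxInfo(mol)
    if not result or not result[1]:
        return None
    aux = result[1]
    marker = "/N:"
    pos = aux.find(marker)
    if pos < 0:
        return None
    numbering = aux[pos + len(marker):].split("/")[0]
    if ";" in numbering:  # multi-component; fall back
        return None
    try:
        order = [int(tok) - 1 for tok in numbering.split(",")]
    except ValueError:
        return None
    if sorted(order) != list(range(mol.GetNumAtoms())):
        return None
    # order[i] = original index of the atom ranked i by InChI; invert for RenumberAtoms
    renumbered = Chem.RenumberAtoms(mol, order)
    return Chem.MolToSmiles(renumbered, canonical=False)


def _inchified_smiles(mol: Chem.Mol) -> str | None:
    text = inchi.MolToInchi(mol)
    if not text:
        return None
    back = inchi.MolFromInchi(text)
    if back is None:
        return None
    return Chem.MolToSmiles(back)


def _kekulized_smiles(mol: Chem.Mol) -> str | None:
    m = Chem.Mol(mol)
    try:
        Chem.Kekulize(m, clearAromaticFlags=True)
    except Chem.KekulizeException:
        return None
    return Chem.MolToSmiles(m, kekuleSmiles=True)


def _explicit_h_smiles(mol: Chem.Mol) -> str:
    return Chem.MolToSmiles(mol, allHsExplicit=True)


def _dative_smiles(mol: Chem.Mol) -> str | None:
    """Rewrite adjacent (+,-) charge pairs as dative bonds where possible."""
    rw = Chem.RWMol(mol)
    changed = False
    for bond in rw.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE:
            continue
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.GetFormalCharge() == 1 and b.GetFormalCharge() == -1:
            donor, acceptor = a, b
        elif a.GetFormalCharge() == -1 and b.GetFormalCharge() == 1:
            donor, acceptor = b, a
        else:
            continue
        bond.SetBondType(Chem.BondType.DATIVE)
        if bond.GetBeginAtomIdx() != donor.GetIdx():
            bond.SetBeginAtomIdx(donor.GetIdx())
            bond.SetEndAtomIdx(acceptor.GetIdx())
        donor.SetFormalCharge(0)
        acceptor.SetFormalCharge(0)
        changed = True
    if not changed:
        return None
    try:
        Chem.SanitizeMol(rw)
    except Exception:
        return None
    return Chem.MolToSmiles(rw)


def enumerate_smiles_variants(
    mol: StandardizedMolecule,
    cfg: AugmentationConfig | None = None,
    log: AugmentationLog | None = None,
) -> set[tuple[str, VariantKind]]:
    """Enumerate non-tautomer SMILES spellings of a standardized structure.

    The canonical form is always present.  Every returned string re-parses to
    the parent's full InChIKey; generation failures for a kind are skipped
    and logged rather than fatal.  Duplicates by string equality are removed
    (the first kind to produce a string, in declaration order, keeps it).
    """
    cfg = cfg or AugmentationConfig()
    log = log if log is not None else AugmentationLog()
    parent = mol_from_smiles(mol.canonical_smiles)
    parent_key = mol.inchikey

    candidates: list[tuple[VariantKind, str | None]] = [
        (VariantKind.canonical, mol.canonical_smiles),
        (VariantKind.aromatic, Chem.MolToSmiles(parent)),
    ]
    for kind, fn in (
        (VariantKind.universal, _universal_smiles),
        (VariantKind.inchified, _inchified_smiles),
        (VariantKind.kekulized, _kekulized_smiles),
        (VariantKind.explicit_h, _explicit_h_smiles),
        (VariantKind.dative, _dative_smiles),
    ):
        try:
            candidates.append((kind, fn(parent)))
        except Exception as exc:  # enumeration failure is non-fatal
            log.skip(parent_key, kind.value, repr(exc))
            candidates.append((kind, None))

    seen: set[str] = set()
    out: set[tuple[str, VariantKind]] = set()
    for kind, smi in candidates:
        if kind not in cfg.include_kinds:
            continue
        if smi is None:
            if kind not in (VariantKind.dative,):  # dative legitimately absent
                log.skip(parent_key, kind.value, "generation returned nothing")
            continue
        if smi in seen:
            continue
        try:
            back = mol_from_smiles(smi)
        except Exception:
            log.skip(parent_key, kind.value, "variant does not re-parse")
            continue
        if _inchikey(back) != parent_key:
            log.skip(parent_key, kind.value, "InChIKey round-trip mismatch")
            continue
        seen.add(smi)
        out.add((smi, kind))
    return out


@lru_cache(maxsize=100_000)
def _valid_tautomers(
    canonical_smiles: str,
    formula: str,
    skeleton: str,
    heavy_atoms: int,
    max_raw: int,
) -> tuple[str, ...]:
    """Deterministic (seed-free) tautomer enumeration, memoized.

    Rule-based enumeration is the expensive step and depends only on the
    structure; the random cap is applied by the caller.
    """
    try:
        parent = mol_from_smiles(canonical_smiles)
        enumerator = rdMolStandardize.TautomerEnumerator()
        enumerator.SetMaxTautomers(max_raw)
        enumerator.SetMaxTransforms(4 * max_raw)
        results = enumerator.Enumerate(parent)
        smiles = sorted({Chem.MolToSmiles(t) for t in results})
    except Exception:
        return ()
    valid = []
    for smi in smiles:
        try:
            t = mol_from_smiles(smi)
        except Exception:
            continue
        if rdMolDescriptors.CalcMolFormula(t) != formula:
            continue
        if t.GetNumHeavyAtoms() != heavy_atoms:
            continue
        if _inchikey(t)[:14] != skeleton:
            continue
        valid.append(smi)
    return tuple(valid)


def enumerate_tautomers(
    mol: StandardizedMolecule,
    cap: int = 50,
    rng_seed: int = 0,
    max_raw: int = 512,
) -> list[str]:
    """Enumerate tautomeric forms, randomly capped at ``cap`` per parent.

    Tautomers share the parent's molecular formula and heavy-atom skeleton
    (first 14 InChIKey characters); forms violating either are dropped.  When
    the enumerator yields more than ``cap`` forms, a uniform random subset is
    taken reproducibly from ``rng_seed``.  On enumeration failure the parent
    canonical form alone is returned.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    valid = list(
        _valid_tautomers(
            mol.canonical_smiles,
            mol.molecular_formula,
            mol.inchikey[:14],
            mol.heavy_atom_count,
            max_raw,
        )
    )
    if not valid:
        return [mol.canonical_smiles]
    if len(valid) > cap:
        rng = np.random.default_rng(rng_seed)
        idx = rng.choice(len(valid), size=cap, replace=False)
        valid = [valid[i] for i in sorted(idx)]
    return valid


def augment_parent(
    record: CuratedRecord,
    cfg: AugmentationConfig | None = None,
    rng_seed: int = 0,
    log: AugmentationLog | None = None,
) -> list[AugmentedExample]:
    """All deduplicated variants of one curated chemical, carrying its label."""
    cfg = cfg or AugmentationConfig()
    log = log if log is not None else AugmentationLog()
    std = standardize_structure(record.canonical_smiles)
    examples: list[AugmentedExample] = []
    seen: set[str] = set()
    for smi, kind in sorted(enumerate_smiles_variants(std, cfg, log)):
        if smi in seen:
            continue
        seen.add(smi)
        examples.append(AugmentedExample(smi, record.inchikey, record.logsw, kind))
    if VariantKind.tautomer in cfg.include_kinds:
        for smi in enumerate_tautomers(std, cfg.tautomer_cap, rng_seed, cfg.max_raw_tautomers):
            if smi in seen:
                continue
            seen.add(smi)
            examples.append(
                AugmentedExample(smi, record.inchikey, record.logsw, VariantKind.tautomer)
            )
    return examples


def augment_dataset(
    dataset: CuratedDataset | Iterable[CuratedRecord],
    cfg: AugmentationConfig | None = None,
    rng_seed: int = 0,
) -> tuple[list[AugmentedExample], AugmentationLog]:
    """Augment every chemical of a (training) dataset.

    Deduplication is per parent; identical strings arising for *different*
    parents (e.g. a shared tautomer) are kept with their own labels and
    logged as cross-parent collisions.  Deterministic for a seed: per-parent
    tautomer seeds are derived from ``rng_seed`` and the parent InChIKey.
    """
    cfg = cfg or AugmentationConfig()
    log = AugmentationLog()
    records = dataset.records if isinstance(dataset, CuratedDataset) else list(dataset)
    out: list[AugmentedExample] = []
    owners: dict[str, str] = {}
    for rec in records:
        parent_seed = derive_seed(rng_seed, rec.inchikey)
        examples = augment_parent(rec, cfg, parent_seed, log)
        for ex in examples:
            prior = owners.get(ex.variant_smiles)
            if prior is not None and prior != ex.parent_id:
                log.cross_parent_collisions.append((ex.variant_smiles, prior, ex.parent_id))
            else:
                owners[ex.variant_smiles] = ex.parent_id
            log.per_kind_counts[ex.variant_kind.value] = (
                log.per_kind_counts.get(ex.variant_kind.value, 0) + 1
            )
        out.extend(examples)
    return out, log


def derive_seed(root: int, tag: str) -> int:
    """Derive a stable sub-seed below 2**31 from a root seed and a tag."""
    import hashlib

    digest = hashlib.sha256(f"{root}:{tag}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def write_augmented_csv(examples: Iterable[AugmentedExample], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "variant_smiles": ex.variant_smiles,
                "parent_inchikey": ex.parent_id,
                "label": ex.label,
                "kind": ex.variant_kind.value,
            }
            for ex in examples
        ]
    ).to_csv(path, index=False)


def read_augmented_csv(path: str | Path) -> list[AugmentedExample]:
    df = pd.read_csv(path)
    return [
        AugmentedExample(
            row["variant_smiles"],
            row["parent_inchikey"],
            float(row["label"]),
            VariantKind(row["kind"]),
        )
        for _, row in df.iterrows()
    ]
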