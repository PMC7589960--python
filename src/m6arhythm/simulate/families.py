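"""Synthetic multi-species protein families with retrievable ground truth.

Each family descends from one random ancestral sequence. A speciation copy
is the ancestor mutated at the ortholog rate; within-species duplicates are
mutated from that species' first copy at the paralog rate; transcript
variants (emulating transcriptome-assembly isoform redundancy) are
near-identical copies (< 2% divergence) of an existing family member in a
designated species.

Substitution model: sites i.i.d.; with probability equal to the rate a
residue is replaced by one of the 19 other amino acids, uniformly. This is
deliberately minimal — downstream stages consume only E-values, never
alignments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: divergence used for transcript variants; must stay below the 2% contract
VARIANT_RATE = 0.01


@dataclass(frozen=True)
class FamilySpec:
    """Composition of one planted gene family.

    Parameters
    ----------
    family_name
        Label, e.g. ``"FIP37"``.
    copies_per_species
        Gene copy number per species (0 allowed; species omitted there).
    ancestral_length
        Length of the random ancestral protein, residues (>= 30).
    substitution_rate_ortholog
        Substitutions/site applied on each speciation branch, in [0, 1).
    substitution_rate_paralog
        Substitutions/site applied on each duplication branch, in [0, 1).
    variant_count
        Number of near-identical transcript variants to add.
    variant_species
        Species receiving the variants; default is the species with the
        most copies (ties broken lexicographically).
    """

    family_name: str
    copies_per_species: Mapping[str, int]
    ancestral_length: int = 300
    substitution_rate_ortholog: float = 0.25
    substitution_rate_paralog: float = 0.10
    variant_count: int = 0
    variant_species: Optional[str] = None

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.copies_per_species.values()):
            raise ValueError("copy numbers must be >= 0")
        for r in (self.substitution_rate_ortholog, self.substitution_rate_paralog):
            if not 0.0 <= r < 1.0:
                raise ValueError("substitution rates must lie in [0, 1)")
        if self.ancestral_length < 30:
            raise ValueError("ancestral_length must be >= 30 residues")
        if self.variant_count < 0:
            raise ValueError("variant_count must be >= 0")

    def resolved_variant_species(self) -> Optional[str]:
        if self.variant_species is not None:
            return self.variant_species
        with_copies = {s: c for s, c in self.copies_per_species.items() if c > 0}
        if not with_copies:
            return None
        return min(with_copies, key=lambda s: (-with_copies[s], s))


@dataclass(frozen=True)
class TruthRecord:
    species: str
    family_name: str
    variant_of: Optional[str] = None


@dataclass
class TruthFamilies:
    """Ground-truth assignment ``protein_id -> (species, family, variant_of)``."""

    records: dict[str, TruthRecord] = field(default_factory=dict)

    def add(self, protein_id: str, rec: TruthRecord) -> None:
        if protein_id in self.records:
            raise ValueError(f"duplicate protein id {protein_id!r}")
        if rec.variant_of is not None:
            parent = self.records[rec.variant_of]
            if (parent.species, parent.family_name) != (rec.species, rec.family_name):
                raise ValueError("variant_of must point within the same species and family")
        self.records[protein_id] = rec

    def family_of(self, protein_id: str) -> str:
        return self.records[protein_id].family_name

    def partition(self) -> dict[str, str]:
        """protein_id -> family label (variants inherit the family)."""
        return {pid: rec.family_name for pid, rec in self.records.items()}

    def cross_tab(self):
        """Family × species member counts (variants included), as a DataFrame."""
        import pandas as pd

        rows = [
            {"family_name": r.family_name, "species": r.species}
            for r in self.records.values()
        ]
        df = pd.DataFrame(rows)
        return (
            df.groupby(["family_name", "species"]).size().rename("n_members").reset_index()
        )


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(AMINO_ACIDS, size=length))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate == 0.0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(arr.size) < rate
    if hit.any():
        for i in np.flatnonzero(hit):
            others = AMINO_ACIDS[AMINO_ACIDS != arr[i]]
            arr[i] = rng.choice(others)
    return "".join(arr)


def generate_proteomes(
    specs: list[FamilySpec],
    species: list[str],
    seed: int,
) -> tuple[dict[str, list[SeqRecord]], TruthFamilies]:
    """Generate per-species protein collections for the planted families.

    Returns one list of ``SeqRecord`` per species (IDs
    ``<species>_<family>_<copy>[_v<j>]``) and the :class:`TruthFamilies`
    ground truth. Deterministic for a fixed seed. A family whose total copy
    number is zero is omitted with a logged warning.
    """
    if not species:
        raise ValueError("species list must be non-empty")
    for sp in species:
        if "_" in sp:
            raise ValueError(
                f"species label {sp!r} must not contain '_' (reserved as ID separator)"
            )
    rng = np.random.default_rng(seed)
    proteomes: dict[str, list[SeqRecord]] = {sp: [] for sp in species}
    truth = TruthFamilies()

    for spec in specs:
        total = sum(spec.copies_per_species.get(sp, 0) for sp in species)
        if total == 0:
            logger.warning("family %s has zero total copies; omitted", spec.family_name)
            continue
        ancestor = _random_protein(rng, spec.ancestral_length)
        member_ids_by_species: dict[str, list[str]] = {}
        for sp in species:
            n_copies = spec.copies_per_species.get(sp, 0)
            ids: list[str] = []
            first_copy_seq = None
            for k in range(1, n_copies + 1):
                if k == 1:
                    seq = _mutate(rng, ancestor, spec.substitution_rate_ortholog)
                    first_copy_seq = seq
                else:
                    seq = _mutate(rng, first_copy_seq, spec.substitution_rate_paralog)
                pid = f"{sp}_{spec.family_name}_{k}"
                proteomes[sp].append(SeqRecord(Seq(seq), id=pid, description=""))
                truth.add(pid, TruthRecord(sp, spec.family_name))
                ids.append(pid)
            member_ids_by_species[sp] = ids

        if spec.variant_count > 0:
            vsp = spec.resolved_variant_species()
            parents = member_ids_by_species.get(vsp, [])
            if not parents:
                raise ValueError(
                    f"family {spec.family_name}: variant species {vsp!r} has no copies"
                )
            seq_by_id = {r.id: str(r.seq) for r in proteomes[vsp]}
            for j in range(1, spec.variant_count + 1):
                parent = parents[(j - 1) % len(parents)]
                seq = _mutate(rng, seq_by_id[parent], VARIANT_RATE)
                pid = f"{parent}_v{j}"
                proteomes[vsp].append(SeqRecord(Seq(seq), id=pid, description=""))
                truth.add(pid, TruthRecord(vsp, spec.family_name, variant_of=parent))

    return proteomes, truth
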