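"""Edit candidate models into "mixed" search models.

Given a target alignment, residues of the candidate that align to nothing
are deleted (non-aligned loops and termini), aligned residues whose
amino-acid type differs from the target are truncated to main chain + Cβ
(Cα only when either residue is glycine), and identical residues keep all
their atoms. Residues are renumbered to target numbering. The resulting
search model carries provenance and a deterministic name of the form

    {source_tag}_{pdb_id}_{chain_id}_{prep_method}_{identity:.1f}_{first}-{last}

used as a file stem for edited models.
"""

from __future__ import annotations

import dataclasses
import re

from .homologue_search import AlignmentResult
from .structures_io import AtomicModel, Chain, Residue, Sequence

__all__ = [
    "Provenance",
    "SearchModel",
    "make_mixed_model",
    "name_search_model",
    "parse_search_model_name",
]

MAIN_CHAIN = ("N", "CA", "C", "O")
MAIN_CHAIN_CB = MAIN_CHAIN + ("CB",)


@dataclasses.dataclass
class Provenance:
    source_tag: str
    pdb_id: str
    chain_id: str
    prep_method: str
    identity: float  # percent
    target_range: tuple[int, int]  # 1-based inclusive

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 100.0):
            raise ValueError(f"identity {self.identity} out of [0, 100]")
        for field in ("source_tag", "pdb_id", "chain_id", "prep_method"):
            val = getattr(self, field)
            if not val or "_" in val:
                raise ValueError(f"provenance field {field}={val!r} empty or contains '_'")


@dataclasses.dataclass
class SearchModel:
    model: AtomicModel
    provenance: Provenance

    @property
    def name(self) -> str:
        return name_search_model(self)


def make_mixed_model(
    model: AtomicModel,
    aln: AlignmentResult,
    target: Sequence,
    chain_id: str | None = None,
    provenance: Provenance | None = None,
) -> SearchModel:
    """Apply loop removal and side-chain truncation to one chain.

    ``aln.pairs`` maps 0-based target residue indices to 0-based positions
    in the chain's residue order. Output residues are renumbered to target
    numbering (target index + 1).
    """
    chain = model.chain(chain_id) if chain_id is not None else model.chains[0]
    aligned = {ci: ti for ti, ci in aln.pairs}
    missing = [ci for ci in aligned if ci >= len(chain.residues)]
    if missing:
        raise ValueError(
            f"alignment refers to residues missing from the model chain: "
            f"positions {sorted(missing)} (chain has {len(chain.residues)})"
        )
    new_residues = []
    for ci, res in enumerate(chain.residues):
        if ci not in aligned:
            continue  # non-aligned loop/terminus: delete
        ti = aligned[ci]
        target_aa = target.residues[ti]
        if res.one_letter() == target_aa:
            keep = [dataclasses.replace(a) for a in res.atoms]
        else:
            # mismatch: main chain + CB, or main chain only if either is GLY
            allowed = (
                MAIN_CHAIN
                if (target_aa == "G" or res.one_letter() == "G")
                else MAIN_CHAIN_CB
            )
            keep = [dataclasses.replace(a) for a in res.atoms if a.name in allowed]
        if keep:
            new_residues.append(Residue(ti + 1, res.name, keep))
    edited = AtomicModel([Chain(chain.chain_id, new_residues)])
    if provenance is None:
        first = aln.target_range[0] if aln.pairs else 1
        last = aln.target_range[1] if aln.pairs else 1
        provenance = Provenance(
            "ALN", "xxxx", chain.chain_id or "A", "mixed", aln.identity, (first, last)
        )
    return SearchModel(edited, provenance)


def name_search_model(sm: SearchModel) -> str:
    """Deterministic file-stem name built from provenance."""
    p = sm.provenance
    if not p.pdb_id or not p.source_tag:
        raise ValueError("provenance incomplete")
    return (
        f"{p.source_tag}_{p.pdb_id}_{p.chain_id}_{p.prep_method}"
        f"_{p.identity:.1f}_{p.target_range[0]}-{p.target_range[1]}"
    )


_NAME_RE = re.compile(
    r"^(?P<source_tag>[^_]+)_(?P<pdb_id>[^_]+)_(?P<chain_id>[^_]+)"
    r"_(?P<prep_method>[^_]+)_(?P<identity>\d+(?:\.\d+)?)"
    r"_(?P<first>\d+)-(?P<last>\d+)$"
)


def parse_search_model_name(name: str) -> Provenance:
    m = _NAME_RE.match(name)
    if m is None:
        raise ValueError(f"cannot parse search-model name {name!r}")
    return Provenance(
        m["source_tag"],
        m["pdb_id"],
        m["chain_id"],
        m["prep_method"],
        float(m["identity"]),
        (int(m["first"]), int(m["last"])),
    )
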