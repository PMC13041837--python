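"""Hierarchical subcellular-compartment taxonomy (41 terms).

Localization annotations are encoded as 41 binary features, one per
compartment term. The taxonomy is a forest: annotating a term also sets all
ancestor bits, so bit patterns are monotone along the hierarchy (a gene in the
mitochondrial matrix is also in the mitochondrion).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

# term -> parent (None for roots). 41 terms total.
_DEFAULT_TERMS: dict[str, str | None] = {
    "nucleus": None,
    "nucleoplasm": "nucleus",
    "nucleolus": "nucleus",
    "nuclear_envelope": "nucleus",
    "nuclear_speckles": "nucleus",
    "nuclear_bodies": "nucleus",
    "chromatin": "nucleus",
    "cytosol": None,
    "cytoskeleton": None,
    "actin_filaments": "cytoskeleton",
    "microtubules": "cytoskeleton",
    "centrosome": "microtubules",
    "centriole": "centrosome",
    "intermediate_filaments": "cytoskeleton",
    "mitochondrion": None,
    "mitochondrial_matrix": "mitochondrion",
    "mitochondrial_inner_membrane": "mitochondrion",
    "mitochondrial_outer_membrane": "mitochondrion",
    "mitochondrial_intermembrane_space": "mitochondrion",
    "endoplasmic_reticulum": None,
    "rough_er": "endoplasmic_reticulum",
    "smooth_er": "endoplasmic_reticulum",
    "golgi_apparatus": None,
    "cis_golgi": "golgi_apparatus",
    "trans_golgi": "golgi_apparatus",
    "vesicles": None,
    "endosome": "vesicles",
    "early_endosome": "endosome",
    "late_endosome": "endosome",
    "lysosome": "vesicles",
    "peroxisome": "vesicles",
    "secretory_vesicle": "vesicles",
    "plasma_membrane": None,
    "cell_junction": "plasma_membrane",
    "focal_adhesion": "plasma_membrane",
    "extracellular": None,
    "extracellular_matrix": "extracellular",
    "ribosome": None,
    "proteasome": None,
    "cilium": None,
    "basal_body": "cilium",
}


@dataclass(frozen=True)
class Taxonomy:
    """A forest of compartment terms with parent links.

    ``terms`` preserves insertion order; that order defines the layout of the
    localization bit block in feature vectors.
    """

    parent: dict[str, str | None]
    terms: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", tuple(self.parent))
        for term, par in self.parent.items():
            if par is not None and par not in self.parent:
                raise ValueError(f"unknown parent term {par!r} for {term!r}")

    def __contains__(self, term: str) -> bool:
        return term in self.parent

    def __len__(self) -> int:
        return len(self.parent)

    def ancestors(self, term: str) -> set[str]:
        """All strict ancestors of ``term`` (empty for roots)."""
        out: set[str] = set()
        cur = self.parent[term]
        while cur is not None:
            if cur in out:  # defensive: cycle in config
                raise ValueError(f"cycle in taxonomy at {cur!r}")
            out.add(cur)
            cur = self.parent[cur]
        return out

    def closure(self, terms: set[str] | frozenset[str]) -> frozenset[str]:
        """Terms plus all their ancestors."""
        out: set[str] = set()
        for t in terms:
            if t not in self.parent:
                raise ValueError(f"unknown compartment term {t!r}")
            out.add(t)
            out |= self.ancestors(t)
        return frozenset(out)

    def index(self, term: str) -> int:
        return self.terms.index(term)


def default_taxonomy() -> Taxonomy:
    """The built-in 41-term compartment taxonomy."""
    return Taxonomy(dict(_DEFAULT_TERMS))


def load_taxonomy(path) -> Taxonomy:
    """Load a taxonomy from a YAML list of ``{term: ..., parent: ...}`` entries."""
    with open(path) as fh:
        entries = yaml.safe_load(fh)
    parent = {e["term"]: e.get("parent") for e in entries}
    return Taxonomy(parent)


def dump_taxonomy(tax: Taxonomy, path) -> None:
    entries = [{"term": t, "parent": p} for t, p in tax.parent.items()]
    with open(path, "w") as fh:
        yaml.safe_dump(entries, fh, sort_keys=False)
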