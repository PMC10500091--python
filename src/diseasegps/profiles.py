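"""Disease profiles: annotated phenotype sets plus gene/inheritance links."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

from .ontology import AnnotationCorpus, OntologyError

VALID_MODES = {"AD", "AR", "XLD", "XLR"}

__all__ = ["DiseaseProfile", "load_gene_disease", "build_disease_profiles", "VALID_MODES"]


@dataclass(frozen=True)
class DiseaseProfile:
    """One candidate disorder: phenotype annotations and supporting genes.

    ``modes`` maps each associated gene symbol to its inheritance mode for
    this disease (AD, AR, XLD or XLR).
    """

    disease_id: str
    name: str
    terms: frozenset[str]
    genes: frozenset[str] = frozenset()
    modes: Mapping[str, str] = field(default_factory=dict)


def load_gene_disease(stream: IO[str] | Iterable[str]) -> list[tuple[str, str, str]]:
    """Read a gene–disease association table.

    Tab-delimited with a header row; columns: gene symbol, disease ID,
    inheritance mode.  Returns (gene, disease_id, mode) rows.
    """
    rows: list[tuple[str, str, str]] = []
    header_seen = False
    for raw in stream:
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        if not header_seen:
            header_seen = True
            continue
        cols = line.split("\t")
        if len(cols) < 3:
            raise OntologyError(f"malformed gene-disease row (need 3 columns): {line!r}")
        rows.append((cols[0].strip(), cols[1].strip(), cols[2].strip()))
    return rows


def build_disease_profiles(
    corpus: AnnotationCorpus,
    gene_disease_rows: Iterable[tuple[str, str, str]] = (),
) -> list[DiseaseProfile]:
    """Join phenotype annotations with gene links into DiseaseProfiles.

    Every corpus disease yields a profile even without gene support; gene
    rows for diseases absent from the corpus are ignored (no phenotype
    annotations means no candidate).
    """
    links: dict[str, dict[str, str]] = {}
    for gene, disease_id, mode in gene_disease_rows:
        links.setdefault(disease_id, {})[gene] = mode
    profiles = []
    for disease_id in sorted(corpus.disease_terms):
        modes = links.get(disease_id, {})
        profiles.append(
            DiseaseProfile(
                disease_id=disease_id,
                name=corpus.disease_names.get(disease_id, disease_id),
                terms=corpus.disease_terms[disease_id],
                genes=frozenset(modes),
                modes=dict(modes),
            )
        )
    return profiles
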