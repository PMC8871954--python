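"""Phylum-level presence/absence patterns of 16 outer-membrane genes.

The genes cover the Bam complex (bamA), the Lol pathway (lolB), the Lpt
lipopolysaccharide transport system (lptA-lptG) and the Tol-Pal envelope
integrity system (pal, tolA, tolB, tolQ, tolR, ybgC, ybgF).  Phyla fall into
four recurring distribution patterns:

1. atypical diderms (Cyanobacteria, Deinococcus-Thermus, diderm Firmicutes):
   reduced Lpt/Tol-Pal (cytoplasm-facing components only), no genuine bamA
   except in Deinococcus-Thermus;
2. monoderm Terrabacteria: essentially nothing beyond the near-universal
   lptB and ybgC;
3. true diderms with LPS: bamA plus the outer-membrane-facing lptD/lptE and
   pal/tolB, with the remaining system members varying by phylum (lolB is
   Proteobacteria-only);
4. Thermotogae: bamA but (nearly) nothing else.

Templates are three-valued (present / absent / variable); pattern assignment
minimizes Hamming distance over the non-variable entries.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "OM_GENES",
    "PatternTemplate",
    "DEFAULT_TEMPLATES",
    "PATTERN_TRUTHS",
    "summarize_phylum",
    "assign_pattern",
    "read_presence_matrix",
    "read_hmmer_tblout",
]

OM_GENES = (
    "bamA", "lolB", "lptA", "lptB", "lptC", "lptD", "lptE", "lptF", "lptG",
    "pal", "tolA", "tolB", "tolQ", "tolR", "ybgC", "ybgF",
)

PRESENT, ABSENT, VARIABLE = "present", "absent", "variable"


@dataclass(frozen=True)
class PatternTemplate:
    pattern_id: int
    name: str
    expected: dict  # gene -> present/absent/variable

    def __post_init__(self):
        extra = set(self.expected) - set(OM_GENES)
        if extra or set(OM_GENES) - set(self.expected):
            raise ValueError("template must cover exactly the 16 genes")
        bad = {v for v in self.expected.values()} - {PRESENT, ABSENT, VARIABLE}
        if bad:
            raise ValueError(f"bad template values: {bad}")


def _template(pattern_id, name, present=(), variable=()):
    expected = {g: ABSENT for g in OM_GENES}
    expected.update({g: PRESENT for g in present})
    expected.update({g: VARIABLE for g in variable})
    return PatternTemplate(pattern_id, name, expected)


#: editable seed templates; "variable" marks genes whose status is
#: phylum- or subgroup-dependent within the pattern
DEFAULT_TEMPLATES = (
    _template(1, "atypical diderms",
              present=("lptA", "lptC", "lptF", "lptG", "tolQ", "tolR"),
              variable=("bamA", "lptB", "ybgC")),
    _template(2, "monoderm Terrabacteria",
              variable=("lptB", "ybgC")),
    _template(3, "true diderms with LPS",
              present=("bamA", "lptD", "lptE", "pal", "tolB"),
              variable=("lolB", "lptA", "lptB", "lptC", "lptF", "lptG",
                        "tolA", "tolQ", "tolR", "ybgC", "ybgF")),
    _template(4, "Thermotogae",
              present=("bamA",),
              variable=("lptB", "ybgC")),
)

#: concrete presence vectors used as simulation truths, one representative
#: instantiation of each template (variable entries resolved)
PATTERN_TRUTHS = {
    1: {g: g in {"lptA", "lptB", "lptC", "lptF", "lptG", "tolQ", "tolR", "ybgC"}
        for g in OM_GENES},
    2: {g: g in {"lptB", "ybgC"} for g in OM_GENES},
    3: {g: True for g in OM_GENES},
    4: {g: g in {"bamA", "lptB"} for g in OM_GENES},
}


def read_presence_matrix(matrix_path, taxonomy_path):
    """Boolean genome x gene CSV plus a genome<TAB>phylum taxonomy TSV."""
    matrix = pd.read_csv(matrix_path, index_col=0).astype(bool)
    tax = pd.read_csv(taxonomy_path, sep="\t", header=None,
                      names=["genome", "phylum"], index_col=0)["phylum"]
    return matrix, tax.to_dict()


def read_hmmer_tblout(path, evalue_max: float = 1e-5,
                      min_score: float = 0.0) -> pd.DataFrame:
    """Parse HMMER ``--tblout`` output into (target, query, evalue, score) hits
    passing the filters; one row per surviving hit."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.split()
            target, query = parts[0], parts[2]
            evalue, score = float(parts[4]), float(parts[5])
            if evalue <= evalue_max and score >= min_score:
                rows.append({"target": target, "query": query,
                             "evalue": evalue, "score": score})
    return pd.DataFrame(rows, columns=["target", "query", "evalue", "score"])


def summarize_phylum(matrix: pd.DataFrame, phylum_map: dict,
                     presence_cutoff: float = 0.5,
                     dubious_max_frac: float = 0.1):
    """Phylum x gene presence calls from a genome x gene boolean matrix.

    A gene is called ``present`` in a phylum when the fraction of its genomes
    carrying at least one ortholog reaches *presence_cutoff*; a strictly
    positive fraction at or below *dubious_max_frac* (isolated, possibly
    contaminant occurrences) is flagged ``?``; intermediate fractions are
    ``variable`` (presence in a sub-group only); zero is ``absent``.

    Returns (calls DataFrame, fractions DataFrame).
    """
    unmapped = sorted(set(matrix.index) - set(phylum_map))
    if unmapped:
        raise ValueError(f"genomes without a phylum: {unmapped}")
    phyla = pd.Series({g: phylum_map[g] for g in matrix.index}, name="phylum")
    frac = matrix.groupby(phyla).mean()

    def call(f: float) -> str:
        if f >= presence_cutoff:
            return PRESENT
        if f == 0.0:
            return ABSENT
        if f <= dubious_max_frac:
            return "?"
        return VARIABLE

    calls = frac.map(call) if hasattr(pd.DataFrame, "map") else frac.applymap(call)
    return calls, frac


def assign_pattern(calls: dict | pd.Series,
                   templates=DEFAULT_TEMPLATES) -> tuple[list[int], int]:
    """Assign a phylum's gene calls to the closest pattern template.

    Distance is the Hamming distance over the template's non-variable
    entries; a profile call of ``?`` counts as absent (dubious occurrences
    are not trusted), and profile ``variable`` entries are skipped.  All
    minimizing pattern ids are returned (ties are reported, not broken),
    together with the minimal distance.
    """
    if isinstance(calls, pd.Series):
        calls = calls.to_dict()
    missing = set(OM_GENES) - set(calls)
    if missing:
        raise ValueError(f"calls missing genes: {sorted(missing)}")
    dists = {}
    for tpl in templates:
        d = 0
        for gene in OM_GENES:
            expect = tpl.expected[gene]
            have = calls[gene]
            if expect == VARIABLE or have == VARIABLE:
                continue
            have_present = have in (PRESENT, True, 1)
            if (expect == PRESENT) != have_present:
                d += 1
        dists[tpl.pattern_id] = d
    dmin = min(dists.values())
    winners = sorted(pid for pid, d in dists.items() if d == dmin)
    return winners, dmin


def pattern_table(matrix: pd.DataFrame, phylum_map: dict,
                  templates=DEFAULT_TEMPLATES, presence_cutoff: float = 0.5,
                  dubious_max_frac: float = 0.1) -> pd.DataFrame:
    """Phylum x gene call table with assigned pattern id and distance."""
    calls, _ = summarize_phylum(matrix, phylum_map, presence_cutoff,
                                dubious_max_frac)
    out = calls.copy()
    assigned, dist = [], []
    for phylum in calls.index:
        winners, d = assign_pattern(calls.loc[phylum], templates)
        assigned.append("|".join(map(str, winners)))
        dist.append(d)
    out["pattern"] = assigned
    out["distance"] = dist
    return out
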