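"""Synthetic test inputs: reference mini-terminology, random terminologies,
and a simulated warfarin-dosing cohort.

The real Metathesaurus is license-bound and never required. Three
generators stand in for it:

* :func:`build_reference_fixture` — a hand-built mini-terminology holding
  the documented crosswalk neighborhood (deep-vein thrombosis and its
  ancestors with their semantic types, the ICD-10-CM projection I82.40),
  the multi-parent "bronchitis" motif, the worked search labels, the
  standard demographic/genotype/event code mappings, and the smoking /
  DVT / AMI value sets. Concept identifiers printed in the source tables
  are used verbatim; concepts that exist only to complete the fixture
  carry synthetic ``C9xxxxxx`` identifiers.
* :func:`generate_mini_terminology` — seeded random concept graphs with
  controllable multi-parent fraction, injected cycles, and multi-source
  atom overlap, for oracle-based property tests.
* :func:`generate_avatar_cohort` — a seeded cohort of virtual patients on
  a 90-day warfarin dosing protocol: demographics, CYP2C9/VKORC1
  genotypes, daily doses, and scheduled INR measurements. Doses and INR
  values are bounded random walks — the pipeline needs realistic
  *structure*, not warfarin pharmacokinetics. Every emitted code resolves
  through the reference fixture's local-code map, so transform coverage
  is complete by construction.

All generators are pure functions of their configuration and seed: the
same inputs produce byte-identical files.
"""
from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path

from .errors import ConfigurationError

# ---------------------------------------------------------------------------
# Reference fixture content
# ---------------------------------------------------------------------------

_ST = {
    "Disease or Syndrome": "T047",
    "Pathologic Function": "T046",
    "Finding": "T033",
    "Pharmacologic Substance": "T121",
    "Clinical Drug": "T200",
    "Laboratory Procedure": "T059",
    "Clinical Attribute": "T201",
    "Population Group": "T098",
    "Organism Attribute": "T032",
}

# (cui, source, code, label, suppress_flag)
_REFERENCE_ATOMS = [
    # Demographics (concept-level codes via the Metathesaurus source).
    ("C0015780", "MTH", "C0015780", "Female", "N"),
    ("C0024554", "MTH", "C0024554", "Male gender", "N"),
    ("C0085756", "MTH", "C0085756", "African American", "N"),
    ("C1515945", "MTH", "C1515945", "American Indian or Alaska Native", "N"),
    ("C0078988", "MTH", "C0078988", "Asians", "N"),
    ("C0043157", "MTH", "C0043157", "Caucasians", "N"),
    ("C0086409", "MTH", "C0086409", "Hispanic or Latino", "N"),
    ("C1513907", "MTH", "C1513907", "Native Hawaiian or other Pacific Islander", "N"),
    ("C1532697", "MTH", "C1532697", "Unknown racial group", "N"),
    # Measurements and genotype tests.
    ("C0365282", "LNC", "3137-7", "Body height measured", "N"),
    ("C0365286", "LNC", "3141-9", "Body weight measured", "N"),
    ("C0365285", "LNC", "3139-3", "Body surface area measured", "N"),
    ("C1369580", "LNC", "34714-6", "INR in blood by coagulation assay value", "N"),
    ("C1830800", "LNC", "46724-1", "cyp2c9 gene mutations found [identifier] in blood or tissue by molecular genetics method nominal", "N"),
    ("C2734139", "LNC", "56164-7", "cyp2c9 gene allele 2 [identifier] in blood by molecular genetics method nominal", "N"),
    ("C2734141", "LNC", "56165-4", "cyp2c9 gene allele 3 [identifier] in blood by molecular genetics method nominal", "N"),
    ("C1978717", "LNC", "50722-8", "vkorc1 gene mutations found [identifier] in blood or tissue by molecular genetics method nominal", "N"),
    # Smoking status (Common MU Dataset value set; only 77176002 has a
    # published concept id — the rest are synthetic C93xxxxx).
    ("C0337664", "SNOMEDCT", "77176002", "Smoker", "N"),
    ("C0337672", "SNOMEDCT", "8392000", "Nonsmoker", "N"),
    ("C9300001", "SNOMEDCT", "449868002", "Current every day smoker", "N"),
    ("C9300002", "SNOMEDCT", "428041000124106", "Current some day smoker", "N"),
    ("C9300003", "SNOMEDCT", "8517006", "Former smoker", "N"),
    ("C9300004", "SNOMEDCT", "266919005", "Never smoker", "N"),
    ("C9300005", "SNOMEDCT", "266927001", "Unknown if ever smoked", "N"),
    ("C9300006", "SNOMEDCT", "428071000124103", "Heavy tobacco smoker", "N"),
    ("C9300007", "SNOMEDCT", "428061000124105", "Light tobacco smoker", "N"),
    # Thrombosis / infarction neighborhood.
    ("C0149871", "SNOMEDCT", "128053003", "Deep venous thrombosis", "N"),
    ("C0149871", "ICD10CM", "I82.40", "Acute embolism and thrombosis of unspecified deep veins of lower extremity", "N"),
    ("C0149871", "ICD9CM", "453.40", "Ac DVT/embl unsp deep ves low extrm", "N"),
    ("C0149871", "ICD9CM", "453.40", "Deep vein thrombosis NOS (retired)", "O"),
    ("C1446197", "SNOMEDCT", "413076004", "No past history of venous thrombosis", "N"),
    ("C0155626", "SNOMEDCT", "57054005", "Acute myocardial infarction", "N"),
    ("C0577811", "SNOMEDCT", "301121007", "Myocardial perfusion normal", "N"),
    ("C0040046", "SNOMEDCT", "64156001", "Thrombophlebitis", "N"),
    ("C0042487", "SNOMEDCT", "111293003", "Venous Thrombosis", "N"),
    ("C0042373", "SNOMEDCT", "27550009", "Vascular Diseases", "N"),
    ("C0007222", "SNOMEDCT", "49601007", "Cardiovascular Diseases", "N"),
    ("C0018799", "SNOMEDCT", "56265001", "Heart Diseases", "N"),
    ("C0027051", "SNOMEDCT", "22298006", "Myocardial Infarction", "N"),
    ("C0012634", "SNOMEDCT", "64572001", "Disease", "N"),
    # Multi-parent motif.
    ("C0006277", "SNOMEDCT", "32398004", "Bronchitis", "N"),
    ("C0021311", "SNOMEDCT", "40733004", "Infection", "N"),
    ("C0006261", "SNOMEDCT", "41427001", "Bronchial Diseases", "N"),
    ("C0035204", "SNOMEDCT", "50043002", "Respiratory Tract Diseases", "N"),
    # A hierarchy asserted only by a non-allowed vocabulary.
    ("C9100001", "MDR", "10040790", "Disorder of soft tissue", "N"),
    ("C9100002", "MDR", "10012431", "Dermatologic disorders", "N"),
    # Medication neighborhood (augmentation relations + NDC attribute).
    ("C0043031", "RXNORM", "11289", "Warfarin", "N"),
    ("C9200001", "LNC", "5610-2", "Warfarin [Mass/volume] in Serum or Plasma", "N"),
    ("C9200002", "RXNORM", "855332", "Warfarin Sodium 5 MG Oral Tablet", "N"),
    # Search worked-example labels.
    ("C0010346", "MTH", "C0010346", "Crohn Disease", "N"),
    ("C0010346", "SNOMEDCT", "34000006", "Crohn's disease", "N"),
    ("C9400001", "SNOMEDCT", "397172007", "Crohn's disease of large bowel", "N"),
    ("C0023470", "MTH", "C0023470", "Myeloid Leukemia", "N"),
    ("C0001815", "MTH", "C0001815", "Primary Myelofibrosis", "N"),
    ("C0023467", "MTH", "C0023467", "Leukemia Myelocytic Acute", "N"),
    ("C0392164", "SNOMEDCT", "236406005", "Cystic fibrosis gene carrier", "N"),
    ("C9400002", "SNOMEDCT", "472321009", "Carrier of cystic fibrosis gene mutation", "N"),
    ("C9400003", "ICD10CM", "Z14.1", "Encounter due to being a cystic fibrosis carrier", "N"),
]

_REFERENCE_SEMANTIC_TYPES = {
    "C0015780": ["Organism Attribute"],
    "C0024554": ["Organism Attribute"],
    "C0085756": ["Population Group"],
    "C1515945": ["Population Group"],
    "C0078988": ["Population Group"],
    "C0043157": ["Population Group"],
    "C0086409": ["Population Group"],
    "C1513907": ["Population Group"],
    "C1532697": ["Population Group"],
    "C0365282": ["Clinical Attribute"],
    "C0365286": ["Clinical Attribute"],
    "C0365285": ["Clinical Attribute"],
    "C1369580": ["Laboratory Procedure"],
    "C1830800": ["Laboratory Procedure"],
    "C2734139": ["Laboratory Procedure"],
    "C2734141": ["Laboratory Procedure"],
    "C1978717": ["Laboratory Procedure"],
    "C0337664": ["Finding"],
    "C0337672": ["Finding"],
    "C9300001": ["Finding"],
    "C9300002": ["Finding"],
    "C9300003": ["Finding"],
    "C9300004": ["Finding"],
    "C9300005": ["Finding"],
    "C9300006": ["Finding"],
    "C9300007": ["Finding"],
    "C0149871": ["Disease or Syndrome"],
    "C1446197": ["Finding"],
    "C0155626": ["Disease or Syndrome"],
    "C0577811": ["Finding"],
    "C0040046": ["Disease or Syndrome"],
    # Different semantic type from the origin of the thrombosis expansion:
    "C0042487": ["Pathologic Function"],
    "C0042373": ["Disease or Syndrome"],
    "C0007222": ["Disease or Syndrome"],
    "C0018799": ["Disease or Syndrome"],
    "C0027051": ["Disease or Syndrome"],
    "C0012634": ["Disease or Syndrome"],
    "C0006277": ["Disease or Syndrome"],
    "C0021311": ["Disease or Syndrome"],
    "C0006261": ["Disease or Syndrome"],
    "C0035204": ["Disease or Syndrome"],
    "C9100001": ["Disease or Syndrome"],
    "C9100002": ["Disease or Syndrome"],
    "C0043031": ["Pharmacologic Substance"],
    "C9200001": ["Laboratory Procedure"],
    "C9200002": ["Clinical Drug"],
    "C0010346": ["Disease or Syndrome"],
    "C9400001": ["Disease or Syndrome"],
    "C0023470": ["Disease or Syndrome"],
    "C0001815": ["Disease or Syndrome"],
    "C0023467": ["Disease or Syndrome"],
    "C0392164": ["Finding"],
    "C9400002": ["Finding"],
    "C9400003": ["Finding"],
}

# (child_cui, REL, RELA, parent_cui_or_cui2, source) in file convention:
# rows are CUI1|REL|RELA|CUI2|SAB with REL=PAR meaning CUI2 is the parent.
_REFERENCE_RELATIONS = [
    ("C0149871", "PAR", "isa", "C0040046", "SNOMEDCT"),
    ("C0149871", "PAR", "isa", "C0042487", "SNOMEDCT"),
    ("C0040046", "PAR", "isa", "C0007222", "SNOMEDCT"),
    ("C0042487", "PAR", "isa", "C0042373", "SNOMEDCT"),
    ("C0042373", "PAR", "isa", "C0007222", "SNOMEDCT"),
    ("C0007222", "PAR", "isa", "C0012634", "SNOMEDCT"),
    ("C0155626", "PAR", "isa", "C0027051", "SNOMEDCT"),
    ("C0027051", "PAR", "isa", "C0018799", "SNOMEDCT"),
    ("C0018799", "PAR", "isa", "C0007222", "SNOMEDCT"),
    # Multi-parent motif with a shared ancestor.
    ("C0006277", "PAR", "isa", "C0021311", "SNOMEDCT"),
    ("C0006277", "PAR", "isa", "C0006261", "SNOMEDCT"),
    ("C0021311", "PAR", "isa", "C0012634", "SNOMEDCT"),
    ("C0006261", "PAR", "isa", "C0035204", "SNOMEDCT"),
    ("C0035204", "PAR", "isa", "C0012634", "SNOMEDCT"),
    # Crohn subtype.
    ("C9400001", "PAR", "isa", "C0010346", "SNOMEDCT"),
    # Nonsensical path asserted by a non-allowed vocabulary: excluded from
    # the restricted view.
    ("C0027051", "PAR", "isa", "C9100001", "MDR"),
    ("C9100001", "PAR", "isa", "C9100002", "MDR"),
    # Augmentation relations: the warfarin-concentration test and the
    # warfarin product become children of the Warfarin ingredient.
    ("C9200001", "RO", "measured_by", "C0043031", "LNC"),
    ("C9200002", "RO", "has_ingredient", "C0043031", "RXNORM"),
]

# CUI|ATN|ATV|SAB
_REFERENCE_ATTRIBUTES = [
    ("C0043031", "NDC", "00056-0170-70", "RXNORM"),
    ("C9200002", "NDC", "00056-0170-75", "RXNORM"),
]

#: (local_code, value-or-None, source, code) — the manual mapping of the
#: simulator's variables to standard vocabularies.
REFERENCE_LOCAL_CODE_MAP = [
    ("Gender", "F", "MTH", "C0015780"),
    ("Gender", "M", "MTH", "C0024554"),
    ("Race", "African American", "MTH", "C0085756"),
    ("Race", "Native American", "MTH", "C1515945"),
    ("Race", "Asian", "MTH", "C0078988"),
    ("Race", "White", "MTH", "C0043157"),
    ("Race", "Hispanic or Latino", "MTH", "C0086409"),
    ("Race", "Pacific Islander", "MTH", "C1513907"),
    ("Race", "Other/unknown", "MTH", "C1532697"),
    ("Height", None, "LNC", "3137-7"),
    ("Weight", None, "LNC", "3141-9"),
    ("BSA", None, "LNC", "3139-3"),
    ("INR", None, "LNC", "34714-6"),
    ("Smoker", "Y", "SNOMEDCT", "77176002"),
    ("Smoker", "N", "SNOMEDCT", "8392000"),
    ("DVT", "Y", "SNOMEDCT", "128053003"),
    ("DVT", "N", "SNOMEDCT", "413076004"),
    ("AMI", "Y", "SNOMEDCT", "57054005"),
    ("AMI", "N", "SNOMEDCT", "301121007"),
    ("CYP2C9", None, "LNC", "46724-1"),
    ("CYP2C92", None, "LNC", "56164-7"),
    ("CYP2C93", None, "LNC", "56165-4"),
    ("VKORC1", None, "LNC", "50722-8"),
    ("Warfarin", None, "RXNORM", "11289"),
]

_REFERENCE_VALUE_SETS = [
    {
        "name": "smoking-status",
        "source_standard": "Common MU Dataset smoking status (SNOMED CT)",
        "members": [
            {"cui": "C9300001", "polarity": "positive", "label": "Current every day smoker"},
            {"cui": "C9300002", "polarity": "positive", "label": "Current some day smoker"},
            {"cui": "C9300003", "polarity": "positive", "label": "Former smoker"},
            {"cui": "C9300004", "polarity": "positive", "label": "Never smoker"},
            {"cui": "C0337664", "polarity": "positive", "label": "Smoker, current status unknown"},
            {"cui": "C9300005", "polarity": "positive", "label": "Unknown if ever smoked"},
            {"cui": "C9300006", "polarity": "positive", "label": "Heavy tobacco smoker"},
            {"cui": "C9300007", "polarity": "positive", "label": "Light tobacco smoker"},
        ],
    },
    {
        "name": "dvt-history",
        "source_standard": "SNOMED CT",
        "members": [
            {"cui": "C0149871", "polarity": "positive", "label": "Deep venous thrombosis"},
            {"cui": "C1446197", "polarity": "negative", "label": "No past history of venous thrombosis"},
        ],
    },
    {
        "name": "ami-history",
        "source_standard": "SNOMED CT",
        "members": [
            {"cui": "C0155626", "polarity": "positive", "label": "Acute myocardial infarction"},
            {"cui": "C0577811", "polarity": "negative", "label": "Myocardial perfusion normal"},
        ],
    },
]


@dataclass
class FixtureFiles:
    """In-memory terminology fixture; ``write`` materializes it on disk."""

    concepts: str
    relations: str
    semantic_types: str
    attributes: str = ""
    local_code_map: str = ""
    value_sets: str = ""

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        names = {
            "concepts": "concepts.rrf",
            "relations": "relations.rrf",
            "semantic_types": "semantic_types.rrf",
            "attributes": "attributes.rrf",
            "local_code_map": "local_code_map.json",
            "value_sets": "value_sets.json",
        }
        paths = {}
        for attr, filename in names.items():
            content = getattr(self, attr)
            if not content:
                continue
            path = outdir / filename
            path.write_text(content, encoding="utf-8")
            paths[attr] = path
        return paths


def build_reference_fixture() -> FixtureFiles:
    """The hand-built reference mini-terminology (static content)."""
    import json

    concept_lines = []
    for i, (cui, sab, code, label, suppress) in enumerate(_REFERENCE_ATOMS, start=1):
        concept_lines.append(f"{cui}|ENG|A{i:07d}|{sab}|PT|{code}|{label}|{suppress}")
    relation_lines = [
        f"{cui1}|{rel}|{rela}|{cui2}|{sab}"
        for cui1, rel, rela, cui2, sab in _REFERENCE_RELATIONS
    ]
    semantic_lines = [
        f"{cui}|{_ST[sty]}|{sty}"
        for cui, stys in sorted(_REFERENCE_SEMANTIC_TYPES.items())
        for sty in stys
    ]
    attribute_lines = [f"{cui}|{atn}|{atv}|{sab}" for cui, atn, atv, sab in _REFERENCE_ATTRIBUTES]

    local_map_rows = [
        {"local_code": lc, "value": v, "source": s, "code": c}
        for lc, v, s, c in REFERENCE_LOCAL_CODE_MAP
    ]
    return FixtureFiles(
        concepts="\n".join(concept_lines) + "\n",
        relations="\n".join(relation_lines) + "\n",
        semantic_types="\n".join(semantic_lines) + "\n",
        attributes="\n".join(attribute_lines) + "\n",
        local_code_map=json.dumps(local_map_rows, indent=2) + "\n",
        value_sets=json.dumps(_REFERENCE_VALUE_SETS, indent=2) + "\n",
    )


# ---------------------------------------------------------------------------
# Random mini-terminologies
# ---------------------------------------------------------------------------

_WORDS = (
    "acute chronic benign malignant focal diffuse primary secondary distal "
    "proximal lateral medial anterior posterior mild severe recurrent stable "
    "disorder syndrome lesion finding infection inflammation fracture tumor "
    "stenosis atrophy fibrosis edema necrosis hyperplasia"
).split()

DEFAULT_SEMANTIC_TYPE_POOL = (
    "Disease or Syndrome",
    "Pathologic Function",
    "Finding",
    "Laboratory Procedure",
)


@dataclass
class FixtureSpec:
    """Parameters of a randomized synthetic terminology."""

    n_concepts: int = 30
    n_sources: int = 3
    multi_parent_fraction: float = 0.2
    cycle_count: int = 0
    semantic_type_pool: tuple[str, ...] = DEFAULT_SEMANTIC_TYPE_POOL
    seed: int = 0

    def validate(self) -> None:
        if self.n_concepts < 0 or self.n_sources < 1:
            raise ConfigurationError("n_concepts must be >= 0 and n_sources >= 1")
        if not 0.0 <= self.multi_parent_fraction <= 1.0:
            raise ConfigurationError("multi_parent_fraction must be in [0, 1]")
        if self.cycle_count < 0:
            raise ConfigurationError("cycle_count must be >= 0")
        if self.cycle_count > max(0, self.n_concepts - 1):
            raise ConfigurationError(
                f"cannot inject {self.cycle_count} cycles into {self.n_concepts} concepts"
            )
        if not self.semantic_type_pool:
            raise ConfigurationError("semantic_type_pool must not be empty")


def generate_mini_terminology(spec: FixtureSpec) -> FixtureFiles:
    """Random concept graph in the store's file dialect.

    Concepts ``C70…`` form a layered DAG skeleton (node i may only have
    parents among nodes < i); ``multi_parent_fraction`` of the non-root
    nodes receive a second parent, and ``cycle_count`` back-edges are added
    on top of existing edges to create hierarchical loops. Every concept
    carries one atom per randomly chosen subset of sources.
    """
    spec.validate()
    rng = random.Random(spec.seed)
    sources = [f"SAB{i + 1}" for i in range(spec.n_sources)]
    cuis = [f"C70{i:05d}" for i in range(spec.n_concepts)]

    concept_lines = []
    semantic_lines = []
    atom_id = 0
    for i, cui in enumerate(cuis):
        k = rng.randint(1, spec.n_sources)
        for sab in rng.sample(sources, k):
            atom_id += 1
            label = f"{rng.choice(_WORDS)} {rng.choice(_WORDS)} {i}"
            concept_lines.append(
                f"{cui}|ENG|A{atom_id:07d}|{sab}|PT|{sab}-{i}|{label}|N"
            )
        sty = rng.choice(spec.semantic_type_pool)
        semantic_lines.append(f"{cui}|T000|{sty}")

    relation_rows: list[tuple[str, str]] = []  # (child, parent)
    for i in range(1, len(cuis)):
        first = rng.randrange(i)
        parents = {first}
        if i >= 2 and rng.random() < spec.multi_parent_fraction:
            extra = rng.randrange(i - 1)
            parents.add(extra if extra < first else extra + 1)
        for p in parents:
            relation_rows.append((cuis[i], cuis[p]))
    for _ in range(spec.cycle_count):
        if not relation_rows:
            break
        child, parent = relation_rows[rng.randrange(len(relation_rows))]
        relation_rows.append((parent, child))  # close a loop

    relation_lines = [
        f"{child}|PAR|isa|{parent}|{rng.choice(sources)}"
        for child, parent in relation_rows
    ]
    return FixtureFiles(
        concepts="\n".join(concept_lines) + "\n" if concept_lines else "",
        relations="\n".join(relation_lines) + "\n" if relation_lines else "",
        semantic_types="\n".join(semantic_lines) + "\n" if semantic_lines else "",
    )


# ---------------------------------------------------------------------------
# Avatar cohort
# ---------------------------------------------------------------------------

#: Variables emitted once per patient at protocol start, in output order.
FIXED_VARIABLES = (
    "Gender", "Race", "Smoker", "DVT", "AMI",
    "CYP2C9", "VKORC1", "Height", "Weight", "BSA",
)

_DEFAULT_SEX = (("F", 0.5), ("M", 0.5))
# Rough US-cohort race mix over the simulator's categories.
_DEFAULT_RACE = (
    ("White", 0.70),
    ("African American", 0.12),
    ("Asian", 0.05),
    ("Native American", 0.01),
    ("Pacific Islander", 0.01),
    ("Other/unknown", 0.11),
)
# Approximate European-ancestry allele frequencies for the two warfarin
# pharmacogenes: CYP2C9 *1/*2/*3 and the VKORC1 -1639 G/A promoter variant.
_DEFAULT_CYP2C9 = (("*1", 0.80), ("*2", 0.12), ("*3", 0.08))
_DEFAULT_VKORC1 = (("G", 0.60), ("A", 0.40))


@dataclass
class AvatarConfig:
    """Stated world of the simulated warfarin-dosing cohort."""

    n_patients: int = 100
    protocol_days: int = 90
    seed: int = 0
    sex_distribution: tuple = _DEFAULT_SEX
    race_distribution: tuple = _DEFAULT_RACE
    cyp2c9_allele_frequencies: tuple = _DEFAULT_CYP2C9
    vkorc1_allele_frequencies: tuple = _DEFAULT_VKORC1
    inr_schedule: tuple[int, ...] | None = None  # default: every 3rd day
    smoker_probability: float = 0.20
    dvt_probability: float = 0.10
    ami_probability: float = 0.05
    start_date: str = "2013-01-01"
    protocol_name: str = "warfarin-dosing-90d"

    def schedule(self) -> tuple[int, ...]:
        if self.inr_schedule is not None:
            return tuple(self.inr_schedule)
        return tuple(range(3, self.protocol_days + 1, 3))

    def records_per_patient(self) -> int:
        return len(FIXED_VARIABLES) + self.protocol_days + len(self.schedule())

    def validate(self) -> None:
        if self.n_patients < 0 or self.protocol_days < 0:
            raise ConfigurationError("n_patients and protocol_days must be >= 0")
        for name, dist in (
            ("sex_distribution", self.sex_distribution),
            ("race_distribution", self.race_distribution),
            ("cyp2c9_allele_frequencies", self.cyp2c9_allele_frequencies),
            ("vkorc1_allele_frequencies", self.vkorc1_allele_frequencies),
        ):
            probs = [p for _, p in dist]
            if any(not 0.0 <= p <= 1.0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
                raise ConfigurationError(f"{name} must be probabilities summing to 1")
        for name, p in (
            ("smoker_probability", self.smoker_probability),
            ("dvt_probability", self.dvt_probability),
            ("ami_probability", self.ami_probability),
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if any(d < 0 or d > self.protocol_days for d in self.schedule()):
            raise ConfigurationError("inr_schedule days must lie within the protocol")


def _pick(rng: random.Random, distribution) -> str:
    x = rng.random()
    acc = 0.0
    for value, p in distribution:
        acc += p
        if x < acc:
            return value
    return distribution[-1][0]


def generate_avatar_cohort(config: AvatarConfig) -> str:
    """Simulated observation TSV for ``config.n_patients`` virtual patients.

    Per patient: one record per fixed demographic/genotype variable at day
    0, one warfarin dose record per protocol day, and one INR record per
    scheduled measurement day. Returns the file contents as text.
    """
    import datetime as _dt

    config.validate()
    rng = random.Random(config.seed)
    start = _dt.date.fromisoformat(config.start_date)
    schedule = config.schedule()

    lines = ["patient_id\tdate\tsource\tcode\tvalue\tunit\tprotocol"]

    def row(pid, day, code, value, unit=""):
        date = (start + _dt.timedelta(days=day)).isoformat()
        lines.append(f"{pid}\t{date}\tLOCAL\t{code}\t{value}\t{unit}\t{config.protocol_name}")

    for i in range(config.n_patients):
        pid = f"p{i + 1:05d}"
        sex = _pick(rng, config.sex_distribution)
        race = _pick(rng, config.race_distribution)
        smoker = "Y" if rng.random() < config.smoker_probability else "N"
        dvt = "Y" if rng.random() < config.dvt_probability else "N"
        ami = "Y" if rng.random() < config.ami_probability else "N"
        cyp = "/".join(
            sorted(_pick(rng, config.cyp2c9_allele_frequencies) for _ in range(2))
        )
        vko = "/".join(
            sorted(_pick(rng, config.vkorc1_allele_frequencies) for _ in range(2))
        )
        height = round(rng.gauss(163.0 if sex == "F" else 177.0, 7.0), 1)
        weight = round(rng.gauss(70.0 if sex == "F" else 85.0, 12.0), 1)
        bsa = round(0.007184 * (height ** 0.725) * (max(weight, 30.0) ** 0.425), 2)

        values = {
            "Gender": (sex, ""),
            "Race": (race, ""),
            "Smoker": (smoker, ""),
            "DVT": (dvt, ""),
            "AMI": (ami, ""),
            "CYP2C9": (cyp, ""),
            "VKORC1": (vko, ""),
            "Height": (f"{height}", "cm"),
            "Weight": (f"{weight}", "kg"),
            "BSA": (f"{bsa}", "m2"),
        }
        for variable in FIXED_VARIABLES:
            value, unit = values[variable]
            row(pid, 0, variable, value, unit)

        # Daily dose and scheduled INR as bounded random walks.
        dose = 5.0
        inr = 1.0
        for day in range(1, config.protocol_days + 1):
            dose = min(10.0, max(2.5, dose + rng.choice((-0.5, 0.0, 0.0, 0.5))))
            row(pid, day, "Warfarin", f"{dose:.1f}", "mg")
        for day in schedule:
            inr = min(4.5, max(0.8, inr + rng.gauss(0.25 if inr < 2.5 else 0.0, 0.3)))
            row(pid, day, "INR", f"{inr:.2f}", "ratio")

    return "\n".join(lines) + "\n"
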