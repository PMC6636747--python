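"""Synthetic expression datasets under four distribution families.

The benchmark design draws gene expression profiles from normal, log-normal,
Student-t (possibly noncentral, fractional df) and Cauchy distributions.
Each parameter group yields datasets of 10,000 genes x 12 samples (6 cases,
6 controls); 5% of genes (500) are differentially expressed, drawing their
case and control samples from distinct parameter pairs, while the remaining
genes draw every sample from one shared parameter pair.

The built-in design has 25 groups: 9 log-normal, 5 t and 2 Cauchy groups
with fixed published parameter tables, plus 9 normal groups formed by
cross-combining 3 non-DE and 3 DE normal parameter sets (a documented,
editable stand-in on a log2-microarray intensity scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GroupSpec",
    "DatasetSpec",
    "ExpressionDataset",
    "sample_expression",
    "generate_dataset",
    "builtin_design",
    "design_table",
    "generate_design",
]

FAMILIES = ("normal", "lognormal", "t", "cauchy")

#: parameter meaning per family, in (first, second) order
PARAM_NAMES = {
    "normal": ("mean", "sd"),
    "lognormal": ("alpha", "sigma"),  # log-scale location / scale
    "t": ("df", "ncp"),
    "cauchy": ("mu", "lam"),  # location / scale
}


@dataclass(frozen=True)
class GroupSpec:
    """One simulation parameter group: a family plus four parameter pairs."""

    family: str
    group_id: str
    nonde_case: tuple[float, float]
    nonde_control: tuple[float, float]
    de_case: tuple[float, float]
    de_control: tuple[float, float]

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        for pair in (self.nonde_case, self.nonde_control, self.de_case,
                     self.de_control):
            _validate_params(self.family, pair)


@dataclass(frozen=True)
class DatasetSpec:
    """Dataset dimensions: genes, DE fraction and per-class sample counts."""

    n_genes: int = 10_000
    frac_de: float = 0.05
    n_case: int = 6
    n_control: int = 6

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if not 0.0 <= self.frac_de < 1.0:
            raise ValueError("frac_de must lie in [0, 1)")
        if self.n_case + self.n_control < 2:
            raise ValueError("need at least two samples")

    @property
    def n_de(self) -> int:
        return round(self.n_genes * self.frac_de)

    @property
    def n_samples(self) -> int:
        return self.n_case + self.n_control


@dataclass
class ExpressionDataset:
    """Genes x samples matrix with phenotype labels and a ground-truth DE mask."""

    matrix: np.ndarray
    phenotype: np.ndarray          # 1 = case, 0 = control
    de_mask: np.ndarray            # True where the gene is differentially expressed
    group_id: str | None = None
    replicate: int | None = None
    seed: int | None = None
    gene_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.phenotype = np.asarray(self.phenotype, dtype=int)
        self.de_mask = np.asarray(self.de_mask, dtype=bool)
        g, s = self.matrix.shape
        if self.phenotype.size != s or self.de_mask.size != g:
            raise ValueError("matrix shape inconsistent with phenotype/de_mask")
        if not self.gene_ids:
            self.gene_ids = [f"gene{i + 1}" for i in range(g)]
        if not self.sample_ids:
            self.sample_ids = [
                f"{'case' if p else 'ctrl'}{i + 1}"
                for i, p in enumerate(self.phenotype)
            ]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    def copy_with(self, **kw) -> "ExpressionDataset":
        base = dict(matrix=self.matrix, phenotype=self.phenotype,
                    de_mask=self.de_mask, group_id=self.group_id,
                    replicate=self.replicate, seed=self.seed,
                    gene_ids=list(self.gene_ids),
                    sample_ids=list(self.sample_ids))
        base.update(kw)
        return ExpressionDataset(**base)


def _validate_params(family: str, params) -> tuple[float, float]:
    a, b = float(params[0]), float(params[1])
    if family == "normal" and b <= 0:
        raise ValueError("normal sd must be positive")
    if family == "lognormal" and b <= 0:
        raise ValueError("lognormal sigma must be positive")
    if family == "t" and a <= 0:
        raise ValueError("t df must be positive")
    if family == "cauchy" and b <= 0:
        raise ValueError("cauchy scale must be positive")
    return a, b


def sample_expression(family: str, params, size, rng: np.random.Generator) -> np.ndarray:
    """Draw i.i.d. expression values from one distribution family.

    lognormal(alpha, sigma) = exp(Normal(alpha, sigma)); t(df, ncp) is the
    noncentral Student-t sampled by its definition (Z + ncp)/sqrt(V/df) with
    V ~ chi-square(df), which supports fractional df; cauchy(mu, lam) is the
    location-scale Cauchy.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    a, b = _validate_params(family, params)
    if family == "normal":
        return rng.normal(a, b, size)
    if family == "lognormal":
        return rng.lognormal(mean=a, sigma=b, size=size)
    if family == "t":
        z = rng.normal(b, 1.0, size)  # noncentrality shifts the numerator
        v = rng.chisquare(a, size)
        return z / np.sqrt(v / a)
    # cauchy
    return a + b * rng.standard_cauchy(size)


def generate_dataset(group: GroupSpec, spec: DatasetSpec | None = None,
                     rng: np.random.Generator | int | None = None,
                     replicate: int | None = None) -> ExpressionDataset:
    """Simulate one expression dataset for a parameter group.

    DE genes occupy randomized row indices (recorded in ``de_mask``); their
    case columns draw from ``de_case`` and control columns from
    ``de_control``.  Non-DE genes draw case/control columns from the
    corresponding non-DE parameter pairs (identical in the built-in design).
    """
    spec = spec or DatasetSpec()
    seed = rng if isinstance(rng, (int, np.integer)) else None
    rng = np.random.default_rng(rng)
    n_de = spec.n_de
    de_idx = np.sort(rng.choice(spec.n_genes, size=n_de, replace=False))
    de_mask = np.zeros(spec.n_genes, dtype=bool)
    de_mask[de_idx] = True

    matrix = np.empty((spec.n_genes, spec.n_samples))
    case_cols = slice(0, spec.n_case)
    ctrl_cols = slice(spec.n_case, spec.n_samples)
    n_non = spec.n_genes - n_de
    matrix[~de_mask, case_cols] = sample_expression(
        group.family, group.nonde_case, (n_non, spec.n_case), rng)
    matrix[~de_mask, ctrl_cols] = sample_expression(
        group.family, group.nonde_control, (n_non, spec.n_control), rng)
    if n_de:
        matrix[de_mask, case_cols] = sample_expression(
            group.family, group.de_case, (n_de, spec.n_case), rng)
        matrix[de_mask, ctrl_cols] = sample_expression(
            group.family, group.de_control, (n_de, spec.n_control), rng)

    phenotype = np.r_[np.ones(spec.n_case, int), np.zeros(spec.n_control, int)]
    return ExpressionDataset(matrix=matrix, phenotype=phenotype,
                             de_mask=de_mask, group_id=group.group_id,
                             replicate=replicate, seed=seed)


# ---------------------------------------------------------------------------
# Built-in 25-group design
# ---------------------------------------------------------------------------

# log-normal groups: (alpha, sigma) for non-DE, then DE case / DE control
_LOGNORMAL_ROWS = [
    ((5.0, 1.5), (4.5, 1.0), (5.0, 2.0)),
    ((5.0, 1.5), (5.0, 1.0), (6.0, 1.1)),
    ((5.0, 1.5), (6.0, 0.8), (6.5, 1.2)),
    ((5.5, 1.3), (4.5, 1.0), (5.0, 2.0)),
    ((5.5, 1.3), (5.0, 1.0), (6.0, 1.1)),
    ((5.5, 1.3), (6.0, 0.8), (6.5, 1.2)),
    ((7.0, 1.0), (4.5, 1.0), (5.0, 2.0)),
    ((7.0, 1.0), (5.0, 1.0), (6.0, 1.1)),
    ((7.0, 1.0), (6.0, 0.8), (6.5, 1.2)),
]

# t groups: (df, ncp) for non-DE, DE case, DE control
_T_ROWS = [
    ((3.0, 0.0), (3.0, 1.0), (4.0, 0.0)),
    ((4.0, 0.0), (4.0, 1.0), (3.0, 0.0)),
    ((3.0, 3.0), (3.0, 2.0), (4.0, 1.0)),
    ((3.0, 2.0), (3.0, 1.0), (4.0, 0.0)),
    ((1.5, 0.0), (1.5, 0.0), (1.3, 0.5)),
]

# Cauchy groups: (mu, lam) for non-DE, DE case, DE control
_CAUCHY_ROWS = [
    ((1000.0, 10.0), (1000.0, 10.0), (950.0, 9.0)),
    ((100.0, 5.0), (100.0, 5.0), (95.0, 4.0)),
]

# Normal stand-in design: 3 non-DE x 3 DE parameter sets, cross-combined.
# Values are on a log2-microarray-like intensity scale; edit freely.
NORMAL_NONDE = [(7.0, 1.0), (8.0, 1.0), (9.0, 1.2)]
NORMAL_DE = [((7.0, 1.0), (8.0, 1.0)),
             ((7.5, 1.0), (9.0, 1.2)),
             ((8.0, 1.0), (10.0, 1.5))]


def builtin_design(normal_nonde=None, normal_de=None) -> list[GroupSpec]:
    """The 25-group benchmark design (9 normal + 9 log-normal + 5 t + 2 Cauchy).

    The normal groups cross-combine the ``normal_nonde`` and ``normal_de``
    parameter sets (defaults above); the other 16 groups are fixed.
    """
    groups: list[GroupSpec] = []
    for i, nd in enumerate(normal_nonde or NORMAL_NONDE):
        for j, (dc, dctl) in enumerate(normal_de or NORMAL_DE):
            groups.append(GroupSpec("normal", f"normal-{3 * i + j + 1}",
                                    nd, nd, dc, dctl))
    for k, (nd, dc, dctl) in enumerate(_LOGNORMAL_ROWS):
        groups.append(GroupSpec("lognormal", f"lognormal-{k + 1}", nd, nd, dc, dctl))
    for k, (nd, dc, dctl) in enumerate(_T_ROWS):
        groups.append(GroupSpec("t", f"t-{k + 1}", nd, nd, dc, dctl))
    for k, (nd, dc, dctl) in enumerate(_CAUCHY_ROWS):
        groups.append(GroupSpec("cauchy", f"cauchy-{k + 1}", nd, nd, dc, dctl))
    return groups


def dataset_seed(base_seed: int, group_id: str, replicate: int) -> int:
    """Deterministic per-dataset seed derived from (base_seed, group, replicate)."""
    ss = np.random.SeedSequence([int(base_seed),
                                 *(ord(c) for c in str(group_id)),
                                 int(replicate)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def design_table(groups, reps_per_group: int, base_seed: int) -> list[dict]:
    """Enumerate the (group, replicate, seed) rows of a design without
    materializing any dataset."""
    return [
        {"group_id": g.group_id, "family": g.family, "replicate": r,
         "seed": dataset_seed(base_seed, g.group_id, r)}
        for g in groups for r in range(reps_per_group)
    ]


def generate_design(groups, reps_per_group: int = 100,
                    spec: DatasetSpec | None = None, base_seed: int = 0):
    """Yield one dataset per (group, replicate), deterministically seeded."""
    if reps_per_group < 0:
        raise ValueError("reps_per_group must be nonnegative")
    spec = spec or DatasetSpec()
    for g in groups:
        for r in range(reps_per_group):
            yield generate_dataset(g, spec,
                                   rng=dataset_seed(base_seed, g.group_id, r),
                                   replicate=r)
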