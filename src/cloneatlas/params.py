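"""Parameter containers and calibration algebra for the tissue and count simulators.

The tissue simulator is parameterized by published summary statistics
(recombination efficiency, fluorophore bias, founder density, clone-size
moments, singleton and EdU fractions, monoclonal-vessel fractions).  Several
of those are *targets on observables*, not direct simulator knobs; the
derivations that turn them into knobs live here so they are done once,
analytically, and are unit-testable:

* ``founder_division_prob`` -- the probability that a labelled founder divides
  at all, derived from the cell-level singleton fraction ``s`` and the
  conditional mean clone size ``m``:  ``q0 = s*m / (1 - s + s*m)`` is the
  founder-level probability of *not* dividing, and the division probability is
  ``1 - q0``.
* clone-size law -- a shifted negative binomial ``S = 2 + X`` with ``X ~ NB``
  moment-matched to the target mean/SD of clone size (clones have >= 2 cells).
* ``two_anchor_vessel_fraction`` -- the fraction of vessels seeded with two
  independent eligible cells, solved in closed form from the target
  monoclonal-vessel fraction (see :func:`solve_two_anchor_fraction`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

#: Fixed fluorophore vocabulary of the Brainbow2.1 (Confetti) reporter, in the
#: order used by every ``colour_probs`` vector in the package.
COLOURS = ("YFP", "RFP", "nGFP", "mCFP")
#: Token for unlabelled (non-recombined) cells.
NO_COLOUR = "NONE"
COLOUR_VOCAB = COLOURS + (NO_COLOUR,)

REGIONS = ("healthy", "border", "infarct", "remote")


class CapacityError(RuntimeError):
    """Raised when the lattice slab cannot host the requested founders/sizes."""


def _check_prob(x: float, name: str) -> None:
    if not (0.0 <= x <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {x!r}")


def _check_colour_probs(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.shape != (4,):
        raise ValueError(f"colour_probs must be a 4-vector over {COLOURS}, got shape {p.shape}")
    if (p < 0).any():
        raise ValueError("colour_probs entries must be non-negative")
    if abs(p.sum() - 1.0) > 1e-12:
        raise ValueError(f"colour_probs must sum to 1 within 1e-12, got sum {p.sum()!r}")
    return p


@dataclass(frozen=True)
class DivisionLaw:
    """Distribution of the size of a clone conditional on the founder dividing.

    Supported laws:

    ``shifted_negative_binomial``
        ``S = 2 + X`` with ``X ~ NB`` moment-matched so that ``E[S] = mean``
        and ``SD[S] = sd``.  Requires ``sd**2 > mean - 2`` (over-dispersion of
        the shifted part); this accommodates the strongly over-dispersed
        infarct-border case where the SD exceeds the mean.
    ``fixed``
        Every clone has exactly ``mean`` cells (``mean`` integer >= 2).
        Useful for tests and worked examples.
    """

    name: str = "shifted_negative_binomial"
    mean: float = 4.0
    sd: float = 2.1

    def __post_init__(self):
        if self.name not in ("shifted_negative_binomial", "fixed"):
            raise ValueError(f"unknown division law {self.name!r}")
        if self.mean < 2:
            raise ValueError("conditional clone size mean must be >= 2 (a clone has >= 2 cells)")
        if self.name == "shifted_negative_binomial":
            m, v = self.mean - 2.0, self.sd**2
            if v <= m:
                raise ValueError(
                    "shifted NB needs sd**2 > mean - 2; use the 'fixed' law for "
                    "under-dispersed clone sizes"
                )

    @property
    def conditional_mean(self) -> float:
        return float(self.mean)

    def _nb_params(self) -> tuple[float, float]:
        m, v = self.mean - 2.0, self.sd**2
        r = m * m / (v - m)
        p = r / (r + m)
        return r, p

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Draw ``size`` clone sizes (integers >= 2)."""
        if self.name == "fixed":
            return np.full(size, int(round(self.mean)), dtype=np.int64)
        r, p = self._nb_params()
        return 2 + rng.negative_binomial(r, p, size=size).astype(np.int64)

    def scaled(self, factor: float) -> "DivisionLaw":
        """Return a law with mean (and SD, proportionally) scaled by ``factor``."""
        return replace(self, mean=max(2.0 + 1e-9, self.mean * factor), sd=self.sd * factor)


def singleton_cell_to_founder_prob(singleton_cell_fraction: float, conditional_mean: float) -> float:
    """Founder-level non-division probability from the cell-level singleton target.

    If a fraction ``q0`` of founders never divide and dividing founders make
    clones of conditional mean size ``m``, the fraction of labelled *cells*
    that are singletons is ``s = q0 / (q0 + (1 - q0) * m)``.  Inverting:
    ``q0 = s*m / (1 - s + s*m)``.
    """
    s, m = singleton_cell_fraction, conditional_mean
    _check_prob(s, "single_cell_fraction")
    if s == 1.0:
        return 1.0
    return s * m / (1.0 - s + s * m)


def solve_two_anchor_fraction(
    monoclonal_target: float,
    recombination_efficiency: float,
    division_prob: float,
    colour_probs,
) -> float:
    """Fraction of vessels carrying two eligible anchors, from the monoclonal target.

    Vessels carry one or two eligible cells ("anchors"); each anchor
    recombines independently with probability ``eps`` and a labelled founder
    divides with probability ``d``.  A vessel enters the monoclonal /
    polychromatic classification when it holds >= 2 labelled cells:

    * one-anchor vessel: classified iff its founder divided (mass ``c1 = eps*d``),
      and then always monoclonal;
    * two-anchor vessel: classified iff both anchors recombined
      (monochromatic with probability ``P2 = sum(p_c^2)``) or exactly one did
      and divided (monoclonal), masses
      ``c2 = eps^2 + 2*eps*(1-eps)*d`` and ``m2 = eps^2*P2 + 2*eps*(1-eps)*d``.

    With vessel-type weights ``(w1, w2)`` the pooled monoclonal fraction is
    ``M = (w1*c1 + w2*m2) / (w1*c1 + w2*c2)``; solving for ``w2`` given the
    target ``M`` is exact.  Returns 0 when the target is (numerically) 1.
    """
    _check_prob(monoclonal_target, "monoclonal_vessel_target")
    eps, d = recombination_efficiency, division_prob
    p = _check_colour_probs(colour_probs)
    if eps == 0.0:
        return 0.0
    p2 = float(np.sum(p**2))
    c1 = eps * d
    c2 = eps**2 + 2 * eps * (1 - eps) * d
    m2 = eps**2 * p2 + 2 * eps * (1 - eps) * d
    floor = m2 / c2  # monoclonal fraction when every vessel has two anchors
    if monoclonal_target >= 1.0 - 1e-12:
        return 0.0
    if monoclonal_target < floor:
        raise ValueError(
            f"monoclonal_vessel_target {monoclonal_target:.3f} is below the floor "
            f"{floor:.3f} achievable with two-anchor vessels at these colour probabilities"
        )
    if c1 == 0.0:
        # founders never divide: one-anchor vessels are never classified, so
        # the pooled fraction is the floor regardless of the mixture.
        return 1.0
    ratio_w1_w2 = (monoclonal_target * c2 - m2) / (c1 * (1.0 - monoclonal_target))
    return 1.0 / (1.0 + ratio_w1_w2)


@dataclass(frozen=True)
class SimTissueParams:
    """Parameters of the Confetti tissue-map simulator.

    Defaults are the healthy-heart condition; :func:`cloneatlas.presets.tissue_preset`
    builds the healthy and infarct-border presets from the published constants.
    """

    recombination_efficiency: float = 0.466
    # healthy-heart fluorophore bias, renormalized to a probability vector
    colour_probs: tuple = (0.519 / 1.007, 0.257 / 1.007, 0.113 / 1.007, 0.118 / 1.007)
    founder_density: float = 72.3  # expected recombination events per section
    division_law: DivisionLaw = field(default_factory=DivisionLaw)
    single_cell_fraction: float = 0.546  # target fraction of labelled CELLS that are singletons
    edu_window_fraction: float = 0.285  # P(EdU+ | labelled cell)
    edu_total_target: float | None = 0.0009  # EdU+ over all cells incl. non-EC background
    background_cells_per_section: int = 40_000  # non-endothelial compartment (counts only)
    monoclonal_vessel_target: float | None = 0.745
    merger_regime: bool = False
    merger_cluster_rate: float = 0.0  # fraction of anchors planted as adjacent founder pairs
    n_sections: int = 30
    lattice_dims: tuple = (100_000, 4096, 4096)
    section_thickness_um: float = 100.0
    region: str = "healthy"
    seed: int | None = None

    def __post_init__(self):
        _check_prob(self.recombination_efficiency, "recombination_efficiency")
        _check_colour_probs(self.colour_probs)
        _check_prob(self.single_cell_fraction, "single_cell_fraction")
        _check_prob(self.edu_window_fraction, "edu_window_fraction")
        _check_prob(self.merger_cluster_rate, "merger_cluster_rate")
        if self.region not in REGIONS:
            raise ValueError(f"region must be one of {REGIONS}")
        if self.founder_density < 0:
            raise ValueError("founder_density must be non-negative")
        if self.n_sections < 1:
            raise ValueError("n_sections must be >= 1")

    # ---- derived calibration constants -------------------------------------

    @property
    def founder_division_prob(self) -> float:
        q0 = singleton_cell_to_founder_prob(
            self.single_cell_fraction, self.division_law.conditional_mean
        )
        return 1.0 - q0

    @property
    def anchors_per_section(self) -> int:
        """Eligible endothelial cells laid per section.

        Chosen so that the expected number of recombination events per section
        equals ``founder_density`` at the configured recombination efficiency.
        """
        eps = self.recombination_efficiency
        if eps == 0.0:
            return int(round(self.founder_density))
        return int(round(self.founder_density / eps))

    @property
    def two_anchor_vessel_fraction(self) -> float:
        if self.monoclonal_vessel_target is None:
            return 0.0
        return solve_two_anchor_fraction(
            self.monoclonal_vessel_target,
            self.recombination_efficiency,
            self.founder_division_prob,
            self.colour_probs,
        )

    @property
    def expected_labelled_per_section(self) -> float:
        q0 = 1.0 - self.founder_division_prob
        mean_event_size = q0 + (1.0 - q0) * self.division_law.conditional_mean
        return self.founder_density * mean_event_size

    @property
    def background_edu_rate(self) -> float:
        """EdU rate of the non-EC background, derived from ``edu_total_target``."""
        if self.edu_total_target is None or self.background_cells_per_section == 0:
            return 0.0
        lab = self.expected_labelled_per_section
        unlabelled = self.anchors_per_section - self.founder_density
        ec = lab + max(unlabelled, 0.0)
        b = self.background_cells_per_section
        rate = (self.edu_total_target * (ec + b) - self.edu_window_fraction * lab) / b
        return float(min(max(rate, 0.0), 1.0))


@dataclass(frozen=True)
class QCParams:
    """Single-cell QC thresholds.

    Cells with fewer than ``min_genes_per_cell`` detected genes, or a
    mitochondrial transcript fraction strictly above ``max_mito_fraction``,
    are removed.  Boundary semantics: a cell with exactly 400 detected genes
    or exactly 20% mitochondrial reads is retained.
    """

    min_genes_per_cell: int = 400
    max_mito_fraction: float = 0.20
    mito_gene_rule: str | tuple = "mt-"  # prefix, or an explicit tuple of gene names

    def __post_init__(self):
        if self.min_genes_per_cell < 0:
            raise ValueError("min_genes_per_cell must be >= 0")
        _check_prob(self.max_mito_fraction, "max_mito_fraction")


def resolve_mito_genes(var_names, rule) -> list:
    """Resolve the mitochondrial gene set from a prefix or explicit list."""
    names = list(var_names)
    if isinstance(rule, str):
        return [g for g in names if g.lower().startswith(rule.lower())]
    wanted = set(rule)
    return [g for g in names if g in wanted]
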