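"""Zero-inflated log-normal OTU simulator with association spike-in.

Each taxon j has marginal parameters (mu_j, sigma_j, pi_j): with probability
pi_j the taxon is absent (abundance 0), otherwise its absolute abundance is
exp(Normal(mu_j, sigma_j^2)).  Known pairwise associations are injected by
coupling pairs of taxa to a shared standard-normal covariate Z drawn once
per sample: for a spiked pair (j, k, t) with effect size beta,

    mu_j'  = mu_j + beta * Z          mu_k' = mu_k + t * beta * Z
    logit(1 - pi_j') = logit(1 - pi_j) + beta * Z     (and t*beta*Z for k)

so t = +1 enforces a positive and t = -1 a negative correlation between the
pair's log abundances and presence patterns.  Pairs sharing a taxon induce
additional (not directly enforced) correlations among their partners, which
the ground-truth record tracks separately.

The built-in study designs (Cases 1-3) mirror a spike-in complexity ladder:
a single anchor taxon coupled to 2, 3 or 4 partner taxa with alternating
signs, against a control group simulated without any spike-in.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .io_otu import OtuTable, kept_taxa_mask, to_relative_abundance

#: Default prevalence/abundance filter applied to the combined control+case
#: table: relative abundance > 1e-4 in at least 30% of samples.
FILTER_MIN_PREVALENCE = 0.30
FILTER_MIN_REL_ABUNDANCE = 1e-4

#: Minimum presence fraction for a taxon to be eligible as a spike-in anchor.
ANCHOR_MIN_PRESENCE = 0.5


@dataclass
class MarginalParams:
    """Per-taxon zero-inflated log-normal marginals.

    mu: mean of the non-zero log absolute abundance.
    sigma: standard deviation of the non-zero log abundance (> 0).
    pi: absence probability in [0, 1].
    """

    mu: np.ndarray
    sigma: np.ndarray
    pi: np.ndarray
    taxon_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        if not (self.mu.shape == self.sigma.shape == self.pi.shape):
            raise ValueError("mu, sigma, pi must have identical shapes")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive")
        if np.any((self.pi < 0) | (self.pi > 1)):
            raise ValueError("pi must lie in [0, 1]")
        if self.taxon_ids is None:
            self.taxon_ids = [f"Feature{j + 1}" for j in range(self.mu.size)]
        if len(self.taxon_ids) != self.mu.size:
            raise ValueError("taxon_ids length mismatch")

    @property
    def n_taxa(self) -> int:
        return self.mu.size


@dataclass
class SpikeinSpec:
    """Pairs of taxa coupled to a shared standard-normal covariate.

    pairs: list of (j, k, t) with taxon indices j, k and direction
    t in {-1, +1}; beta is the common effect size.
    """

    pairs: list[tuple[int, int, int]] = field(default_factory=list)
    beta: float = 1.0

    def __post_init__(self) -> None:
        for j, k, t in self.pairs:
            if t not in (-1, 1):
                raise ValueError(f"direction must be -1 or +1, got {t}")
            if j == k:
                raise ValueError("a pair must couple two distinct taxa")

    def spiked_taxa(self) -> set[int]:
        out: set[int] = set()
        for j, k, _ in self.pairs:
            out.update((j, k))
        return out


@dataclass
class SimulatedStudy:
    """A control/case pair of OTU tables with known association ground truth."""

    control: OtuTable
    case: OtuTable
    truth: dict

    def to_json(self) -> str:
        return json.dumps(self.truth, indent=2)


def default_marginals(n_taxa: int = 100) -> MarginalParams:
    """Default marginal fixture emulating a realistic abundance/prevalence
    gradient: log-mean abundance spaced from 6 down to 0, unit log-sd, and
    absence probability rising from 0.05 to 0.8 along the same axis, so
    abundant taxa are also the most prevalent (the usual abundance-
    occupancy relationship in microbiome surveys)."""
    mu = np.linspace(6.0, 0.0, n_taxa)
    sigma = np.ones(n_taxa)
    pi = np.linspace(0.05, 0.8, n_taxa)
    return MarginalParams(mu=mu, sigma=sigma, pi=pi)


def apply_spikein(
    params: MarginalParams, spec: SpikeinSpec, z: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Shift marginals per sample according to the spike-in equations.

    ``z`` holds one covariate value per sample (shared by the mean and the
    presence equations and by every pair within that sample).  Returns the
    per-sample ``(mu, pi)`` arrays of shape (n_samples, n_taxa); sigma is
    untouched by the spike-in.
    """
    z = np.atleast_1d(np.asarray(z, dtype=float))
    n = z.size
    mu = np.tile(params.mu, (n, 1))
    # accumulate log-odds of presence, then invert; log((1-pi)/pi) is +-inf
    # at the boundaries, which only matters for taxa actually spiked
    with np.errstate(divide="ignore"):
        logit_presence = np.tile(
            np.log(1.0 - params.pi) - np.log(params.pi), (n, 1)
        )
    for j, k, t in spec.pairs:
        for idx, tt in ((j, 1), (k, t)):
            if params.pi[idx] in (0.0, 1.0):
                raise ValueError(
                    f"taxon index {idx} has absence probability {params.pi[idx]}; "
                    "presence log-odds undefined for spike-in"
                )
            mu[:, idx] += tt * spec.beta * z
            logit_presence[:, idx] += tt * spec.beta * z
    with np.errstate(over="ignore"):
        presence = 1.0 / (1.0 + np.exp(-logit_presence))
    pi = 1.0 - presence
    return mu, pi


def _draw_table(
    mu: np.ndarray,
    sigma: np.ndarray,
    pi: np.ndarray,
    rng: np.random.Generator,
    sample_prefix: str,
    taxon_ids: list[str],
) -> OtuTable:
    n, p = mu.shape
    absent = rng.random((n, p)) < pi
    logx = rng.normal(mu, sigma[None, :])
    x = np.exp(logx)
    x[absent] = 0.0
    return OtuTable(
        sample_ids=[f"{sample_prefix}{i + 1}" for i in range(n)],
        taxon_ids=list(taxon_ids),
        abundance=x,
    )


def simulate_baseline(
    params: MarginalParams, n_samples: int, seed: int, sample_prefix: str = "S"
) -> OtuTable:
    """Simulate independent zero-inflated log-normal abundances (no spike-in)."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    p = params.n_taxa
    mu = np.tile(params.mu, (n_samples, 1))
    pi = np.tile(params.pi, (n_samples, 1))
    return _draw_table(mu, params.sigma, pi, rng, sample_prefix, params.taxon_ids)


def simulate_spiked(
    params: MarginalParams,
    spec: SpikeinSpec,
    n_samples: int,
    seed: int,
    sample_prefix: str = "S",
) -> OtuTable:
    """Simulate a table with covariate-mediated association spike-in.

    One standard-normal covariate is drawn per sample and shared across all
    spiked pairs and both spike-in equations.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n_samples)
    mu, pi = apply_spikein(params, spec, z)
    return _draw_table(mu, params.sigma, pi, rng, sample_prefix, params.taxon_ids)


def select_anchors(
    baseline: OtuTable, n_anchors: int = 5, min_presence: float = ANCHOR_MIN_PRESENCE
) -> list[int]:
    """Pick spike-in anchors: the most abundant taxa (by mean relative
    abundance in a baseline run) present in at least ``min_presence`` of
    samples."""
    rel = to_relative_abundance(baseline).abundance
    presence = (baseline.abundance > 0).mean(axis=0)
    mean_rel = rel.mean(axis=0)
    eligible = np.flatnonzero(presence >= min_presence)
    if eligible.size < n_anchors:
        raise ValueError(
            f"only {eligible.size} taxa are present in >= {min_presence:.0%} of "
            f"samples; {n_anchors} spike-in anchors required"
        )
    order = eligible[np.argsort(mean_rel[eligible])[::-1]]
    return [int(i) for i in order[:n_anchors]]


def case_pairs(case_number: int, anchors: list[int]) -> list[tuple[int, int, int]]:
    """Enforced pairs for the three study designs: the first anchor F1 is
    coupled to F2..F5 with alternating directions (+, -, +, -)."""
    if case_number not in (1, 2, 3):
        raise ValueError("case_number must be 1, 2 or 3")
    f1, f2, f3, f4, f5 = anchors[:5]
    pairs = [(f1, f2, +1), (f1, f3, -1)]
    if case_number >= 2:
        pairs.append((f1, f4, +1))
    if case_number == 3:
        pairs.append((f1, f5, -1))
    return pairs


def induced_pairs(pairs: list[tuple[int, int, int]]) -> list[tuple[int, int, int]]:
    """Correlations induced (not enforced) among partners sharing an anchor:
    partners j, k of a common anchor become correlated with sign t_j * t_k."""
    partners: dict[int, list[tuple[int, int]]] = {}
    for j, k, t in pairs:
        partners.setdefault(j, []).append((k, t))
    out = []
    for anchor, plist in partners.items():
        for a in range(len(plist)):
            for b in range(a + 1, len(plist)):
                (ka, ta), (kb, tb) = plist[a], plist[b]
                out.append((ka, kb, ta * tb))
    return out


def build_case(
    case_number: int,
    params: MarginalParams | None = None,
    n_samples: int = 100,
    beta: float = 1.0,
    seed: int = 0,
    apply_filter: bool = True,
) -> SimulatedStudy:
    """Simulate a matched control/case study with known spike-in structure.

    A baseline run (no spike-in) selects the anchors; the control table
    repeats the baseline procedure with a fresh seed stream, the case table
    adds the spike-in for the requested design.  Both tables are then
    restricted to taxa passing the prevalence/abundance filter computed on
    the combined control+case table (relative abundance > 1e-4 in >= 30% of
    samples), so the returned taxon sets are identical.
    """
    if params is None:
        params = default_marginals()
    ss = np.random.SeedSequence(seed)
    seed_anchor, seed_control, seed_case = (
        int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(3)
    )
    baseline = simulate_baseline(params, n_samples, seed_anchor)
    anchors = select_anchors(baseline)
    pairs = case_pairs(case_number, anchors)
    spec = SpikeinSpec(pairs=pairs, beta=beta)
    control = simulate_baseline(params, n_samples, seed_control, sample_prefix="C")
    case = simulate_spiked(params, spec, n_samples, seed_case, sample_prefix="D")

    if apply_filter:
        combined = OtuTable(
            sample_ids=control.sample_ids + case.sample_ids,
            taxon_ids=list(params.taxon_ids),
            abundance=np.vstack([control.abundance, case.abundance]),
        )
        mask = kept_taxa_mask(
            to_relative_abundance(combined),
            FILTER_MIN_PREVALENCE,
            FILTER_MIN_REL_ABUNDANCE,
        )
        # anchors always survive the 30% screen (they are >= 50% present)
        control = control.select_taxa(mask)
        case = case.select_taxa(mask)
        old_to_new = {int(o): n for n, o in enumerate(np.flatnonzero(mask))}
    else:
        old_to_new = {j: j for j in range(params.n_taxa)}

    def remap(prs):
        return [
            (old_to_new[j], old_to_new[k], t)
            for j, k, t in prs
            if j in old_to_new and k in old_to_new
        ]

    truth = {
        "case_number": case_number,
        "beta": beta,
        "seed": seed,
        "taxon_ids": list(control.taxon_ids),
        "anchors": [old_to_new[a] for a in anchors if a in old_to_new],
        "enforced_pairs": remap(pairs),
        "induced_pairs": remap(induced_pairs(pairs)),
    }
    return SimulatedStudy(control=control, case=case, truth=truth)
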