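"""Synthetic velvet-like domain families with fully known planted structure.

The generator emulates the statistical shape of a kingdom-wide velvet-domain
collection: two conserved blocks (a ~30-column DNA-binding region and a
~105-column dimerization region split into alpha-subunit, linker and
beta-subunit), a poorly conserved variable region between them whose residue
length ranges from 0 to 450 with its main mass in 40-60, linker lengths
concentrated in 15-25, and a set of near-invariant columns (identity 0.95-0.98)
inside the dimerization subunits.  Every sampled family comes with its ground
truth: the true alignment (match columns plus expanded insert columns), the
per-sequence region spans in residue coordinates, and the realized identity of
every planted invariant site.

Columns are exchangeable given their conservation class; residues are drawn
from a Dirichlet-categorical model (one Dirichlet draw per column, then i.i.d.
residues per sequence).  There is no phylogeny: sequences are independent.
All randomness flows from the single integer seed of the spec.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import stats

from ._alphabet import AMINO_ACIDS, N_AA, resolve_background
from .alignment import MatchAlignment
from .architecture import ArchitectureTemplate, LengthDistribution, Region
from .sequences import DomainSequence


class SpecError(ValueError):
    """Raised when a synthetic family spec fails validation."""


# -- samplers -----------------------------------------------------------------


@dataclass
class VariableLengthSampler:
    """Residue-length distribution of the variable region, support 0..450.

    ``velvet_mixture`` is an atom at 0, a discretized log-normal with mode
    ``lognormal_mode``, and a heavy power-law tail from ``tail_start`` to
    ``max_length``; the log-normal weight is solved so that the probability
    mass on the inclusive ``[range_lo, range_hi]`` equals ``target_mass``
    exactly (the distribution-level calibration of the 47%-in-40..60
    statistic).  ``constant`` is a point mass at ``value``.
    """

    kind: str = "velvet_mixture"
    mass_zero: float = 0.02
    lognormal_mode: float = 50.0
    lognormal_sigma: float = 0.28
    tail_start: int = 80
    tail_exponent: float = 1.5
    max_length: int = 450
    target_mass: float = 0.47
    range_lo: int = 40
    range_hi: int = 60
    value: int = 50

    def pmf(self) -> np.ndarray:
        """Probability mass over lengths 0..max_length."""
        L = self.max_length
        if self.kind == "constant":
            if not 0 <= self.value <= L:
                raise SpecError(f"constant length {self.value} outside 0..{L}")
            p = np.zeros(L + 1)
            p[self.value] = 1.0
            return p
        if self.kind != "velvet_mixture":
            raise SpecError(f"unknown variable length sampler {self.kind!r}")
        if not 0 <= self.mass_zero < 1:
            raise SpecError("mass_zero outside [0, 1)")
        if not 0 < self.target_mass < 1:
            raise SpecError("target_mass outside (0, 1)")
        k = np.arange(1, L + 1, dtype=float)
        # log-normal with the requested mode: mu = ln(mode) + sigma^2
        mu = np.log(self.lognormal_mode) + self.lognormal_sigma**2
        upper = stats.norm.cdf((np.log(k + 0.5) - mu) / self.lognormal_sigma)
        lower = stats.norm.cdf((np.log(k - 0.5) - mu) / self.lognormal_sigma)
        ln_mass = np.concatenate([[0.0], upper - lower])
        ln_mass /= ln_mass.sum()
        tail = np.zeros(L + 1)
        ks = np.arange(self.tail_start, L + 1, dtype=float)
        tail[self.tail_start :] = ks ** (-self.tail_exponent)
        tail /= tail.sum()

        sel = np.zeros(L + 1, dtype=bool)
        sel[self.range_lo : self.range_hi + 1] = True
        m_ln = ln_mass[sel].sum()
        m_tail = tail[sel].sum()
        w_rest = 1.0 - self.mass_zero
        if abs(m_ln - m_tail) < 1e-12:
            raise SpecError("degenerate mixture: components have equal range mass")
        w_ln = (self.target_mass - w_rest * m_tail) / (m_ln - m_tail)
        if not 0.0 <= w_ln <= w_rest:
            raise SpecError(
                f"target_mass {self.target_mass} unreachable with these components"
            )
        p = w_ln * ln_mass + (w_rest - w_ln) * tail
        p[0] += self.mass_zero
        assert abs(p[sel].sum() - self.target_mass) < 1e-9
        return p / p.sum()


@dataclass
class LinkerJitterSampler:
    """Per-sequence insertion/deletion count inside the linker.

    ``two_sided_geometric`` draws a signed jitter J with P(J = j) proportional
    to rho^|j| on the truncated support; rho is solved by bisection so that
    P(|J| <= half_width) equals ``target_mass`` exactly.  With the default
    20-column linker, |J| <= 5 corresponds to linker lengths 15..25.
    """

    kind: str = "two_sided_geometric"
    target_mass: float = 0.63
    half_width: int = 5
    min_jitter: int = -15
    max_jitter: int = 30

    def support_pmf(self) -> tuple[np.ndarray, np.ndarray]:
        values = np.arange(self.min_jitter, self.max_jitter + 1)
        if self.kind == "none":
            probs = (values == 0).astype(float)
            return values, probs
        if self.kind != "two_sided_geometric":
            raise SpecError(f"unknown linker jitter sampler {self.kind!r}")
        if self.min_jitter > -self.half_width or self.max_jitter < self.half_width:
            raise SpecError("jitter support must cover [-half_width, half_width]")

        def mass(rho: float) -> float:
            w = rho ** np.abs(values)
            return w[np.abs(values) <= self.half_width].sum() / w.sum()

        lo_mass = mass(1.0 - 1e-12)
        if not lo_mass < self.target_mass < 1.0:
            raise SpecError(
                f"target_mass {self.target_mass} outside reachable ({lo_mass:.3f}, 1)"
            )
        lo, hi = 1e-12, 1.0 - 1e-12  # mass() is decreasing in rho
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if mass(mid) > self.target_mass:
                lo = mid
            else:
                hi = mid
        rho = 0.5 * (lo + hi)
        probs = rho ** np.abs(values).astype(float)
        return values, probs / probs.sum()


# -- spec ---------------------------------------------------------------------


@dataclass
class BlockLengths:
    """Match-column counts of the five planted regions."""

    dna_binding: int = 30
    variable: int = 50
    alpha: int = 45
    linker: int = 20
    beta: int = 40

    @property
    def total(self) -> int:
        return self.dna_binding + self.variable + self.alpha + self.linker + self.beta


@dataclass
class ColumnClassLevel:
    """Dirichlet parameters of one conservation class.

    ``identity`` is the mean probability of the column's consensus residue;
    ``concentration`` the total Dirichlet concentration (higher = column
    distributions closer to the class mean).
    """

    identity: float
    concentration: float


@dataclass
class InvariantSite:
    """A planted near-invariant column: the residue appears with the stated
    identity probability in every sequence (off-residues drawn from the
    background excluding the residue, so the realized identity estimates the
    probability directly)."""

    column: int      # 1-based match column
    residue: str
    identity: float


DEFAULT_LEVELS = {
    "conserved": ColumnClassLevel(identity=0.50, concentration=400.0),
    "linker": ColumnClassLevel(identity=0.48, concentration=150.0),
    "variable": ColumnClassLevel(identity=0.0, concentration=2000.0),
}

TIGHT_LEVELS = {
    "conserved": ColumnClassLevel(identity=0.95, concentration=500.0),
    "linker": ColumnClassLevel(identity=0.80, concentration=500.0),
    "variable": ColumnClassLevel(identity=0.0, concentration=2000.0),
}

# Residues used for planted sites (no alanine: planted sites are the
# alanine-scan ground truth and native alanines are skipped by the planner).
_SITE_RESIDUES = "GPWDRFNKYSTEIVH"


def default_invariant_sites(blocks: BlockLengths) -> list[InvariantSite]:
    """30 near-invariant dimerization sites: 15 in alpha, 15 in beta.

    One glycine site at identity 0.98 and one leucine site at 0.95 mirror the
    two most conserved residues of the velvet dimerization region; the others
    cycle through common strongly conserved residues at 0.95-0.97.
    """
    a0 = blocks.dna_binding + blocks.variable + 1
    alpha_cols = np.linspace(a0, a0 + blocks.alpha - 1, 15).round().astype(int)
    b0 = a0 + blocks.alpha + blocks.linker
    beta_cols = np.linspace(b0, b0 + blocks.beta - 1, 15).round().astype(int)
    idents = [0.95, 0.96, 0.97]
    sites = []
    for k, col in enumerate(alpha_cols):
        if k == 2:
            sites.append(InvariantSite(int(col), "G", 0.98))
        else:
            sites.append(InvariantSite(int(col), _SITE_RESIDUES[k % len(_SITE_RESIDUES)],
                                       idents[k % 3]))
    for k, col in enumerate(beta_cols):
        if k == 7:
            sites.append(InvariantSite(int(col), "L", 0.95))
        else:
            sites.append(InvariantSite(int(col), _SITE_RESIDUES[(k + 5) % len(_SITE_RESIDUES)],
                                       idents[(k + 1) % 3]))
    return sites


@dataclass
class SyntheticFamilySpec:
    """Complete description of a synthetic velvet-like family."""

    n_sequences: int = 200
    block_lengths: BlockLengths = field(default_factory=BlockLengths)
    variable_length_sampler: VariableLengthSampler = field(
        default_factory=VariableLengthSampler
    )
    linker_jitter_sampler: LinkerJitterSampler = field(
        default_factory=LinkerJitterSampler
    )
    conservation_levels: dict = field(
        default_factory=lambda: {k: ColumnClassLevel(v.identity, v.concentration)
                                 for k, v in DEFAULT_LEVELS.items()}
    )
    invariant_sites: list = None
    background: object = "uniform"
    insert_placement: str = "center"  # or "random"
    seed: int = 0

    def __post_init__(self):
        if self.invariant_sites is None:
            self.invariant_sites = default_invariant_sites(self.block_lengths)

    def validate(self) -> "SyntheticFamilySpec":
        if self.n_sequences < 2:
            raise SpecError(f"n_sequences must be >= 2, got {self.n_sequences}")
        b = self.block_lengths
        for name in ("dna_binding", "variable", "alpha", "linker", "beta"):
            if getattr(b, name) < 1:
                raise SpecError(f"block_lengths.{name} must be positive")
        if b.variable < 2:
            raise SpecError("block_lengths.variable must be >= 2 (insert slots)")
        resolve_background(self.background)
        for cls in ("conserved", "linker", "variable"):
            if cls not in self.conservation_levels:
                raise SpecError(f"conservation_levels missing class {cls!r}")
            lvl = self.conservation_levels[cls]
            if not 0.0 <= lvl.identity <= 1.0:
                raise SpecError(f"conservation_levels[{cls}].identity outside [0, 1]")
            if lvl.concentration <= 0:
                raise SpecError(f"conservation_levels[{cls}].concentration must be > 0")
        total = b.total
        seen = set()
        for s in self.invariant_sites:
            if not 1 <= s.column <= total:
                raise SpecError(f"invariant site column {s.column} outside 1..{total}")
            if s.column in seen:
                raise SpecError(f"duplicate invariant site column {s.column}")
            seen.add(s.column)
            if s.residue not in AMINO_ACIDS:
                raise SpecError(f"invariant site residue {s.residue!r} invalid")
            if not 0.0 <= s.identity <= 1.0:
                raise SpecError(f"invariant site identity {s.identity} outside [0, 1]")
        if self.insert_placement not in ("center", "random"):
            raise SpecError(f"insert_placement must be 'center' or 'random'")
        self.variable_length_sampler.pmf()
        self.linker_jitter_sampler.support_pmf()
        return self

    def template(self) -> ArchitectureTemplate:
        """The planted architecture in match-column space."""
        b = self.block_lengths
        s = 1
        spans = {}
        for name in ("dna_binding", "variable", "alpha", "linker", "beta"):
            w = getattr(b, name)
            spans[name] = (s, s + w - 1)
            s += w
        return ArchitectureTemplate.from_spans(spans, provenance="user-supplied")


def default_spec(n_sequences: int = 200, seed: int = 0, tight: bool = False,
                 **overrides) -> SyntheticFamilySpec:
    """The default study-condition spec; ``tight=True`` raises block
    conservation for boundary-recovery experiments."""
    levels = TIGHT_LEVELS if tight else DEFAULT_LEVELS
    spec = SyntheticFamilySpec(
        n_sequences=n_sequences,
        seed=seed,
        conservation_levels={k: ColumnClassLevel(v.identity, v.concentration)
                             for k, v in levels.items()},
        **overrides,
    )
    return spec.validate()


# -- truth --------------------------------------------------------------------


@dataclass
class FamilyTruth:
    """Everything the generator actually sampled."""

    true_alignment: MatchAlignment
    template: ArchitectureTemplate
    true_architecture: list  # per sequence: {region: (start, end)} residue coords
    true_identity: dict      # (column, residue) -> realized identity fraction
    variable_lengths: np.ndarray
    linker_jitters: np.ndarray

    def to_json(self, path: str | Path) -> None:
        payload = {
            "template": {
                r.name: [r.start, r.end] for r in self.template.regions
            },
            "true_architecture": [
                {k: list(v) for k, v in arch.items()} for arch in self.true_architecture
            ],
            "true_identity": {
                f"{col}:{res}": frac for (col, res), frac in self.true_identity.items()
            },
            "variable_lengths": self.variable_lengths.tolist(),
            "linker_jitters": self.linker_jitters.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


# -- sampling -----------------------------------------------------------------


def _column_classes(spec: SyntheticFamilySpec) -> list[str]:
    b = spec.block_lengths
    classes = (
        ["conserved"] * b.dna_binding
        + ["variable"] * b.variable
        + ["conserved"] * b.alpha
        + ["linker"] * b.linker
        + ["conserved"] * b.beta
    )
    return classes


def sample_family(spec: SyntheticFamilySpec):
    """Sample a family; returns ``(sequences, truth)``.

    Deterministic for a fixed spec and seed.  Each sequence is the
    concatenation DNA-binding + variable + alpha + linker + beta; insertions
    occur only inside the variable region and the linker, the conserved
    blocks are insertion- and deletion-free.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    b = spec.block_lengths
    n = spec.n_sequences
    q = resolve_background(spec.background)
    total = b.total
    site_by_col = {s.column: s for s in spec.invariant_sites}
    classes = _column_classes(spec)

    # 1. per-column residue matrix over match columns
    R = np.empty((n, total), dtype=np.int8)
    for col in range(1, total + 1):
        site = site_by_col.get(col)
        if site is not None:
            r_idx = AMINO_ACIDS.index(site.residue)
            hit = rng.random(n) < site.identity
            off = q.copy()
            off[r_idx] = 0.0
            off /= off.sum()
            draws = rng.choice(N_AA, size=n, p=off)
            R[:, col - 1] = np.where(hit, r_idx, draws)
        else:
            lvl = spec.conservation_levels[classes[col - 1]]
            consensus = int(rng.choice(N_AA, p=q))
            mean = lvl.identity * np.eye(N_AA)[consensus] + (1.0 - lvl.identity) * q
            p_col = rng.dirichlet(lvl.concentration * mean)
            R[:, col - 1] = rng.choice(N_AA, size=n, p=p_col)

    # 2. per-sequence variable-region lengths -> deletions / insertions
    pmf = spec.variable_length_sampler.pmf()
    var_lengths = rng.choice(len(pmf), size=n, p=pmf)
    V = b.variable
    var_del = []   # (start offset within variable region, width) or None
    var_ins = []   # (slot within variable region 1..V-1, count)
    for L in var_lengths:
        if L < V:
            width = V - int(L)
            start = int(rng.integers(0, V - width + 1))
            var_del.append((start, width))
            var_ins.append(None)
        elif L > V:
            extra = int(L) - V
            slot = V // 2 if spec.insert_placement == "center" else int(rng.integers(1, V))
            var_ins.append((slot, extra))
            var_del.append(None)
        else:
            var_del.append(None)
            var_ins.append(None)

    # 3. linker jitter
    jit_vals, jit_probs = spec.linker_jitter_sampler.support_pmf()
    jitters = rng.choice(jit_vals, size=n, p=jit_probs)
    K = b.linker
    link_del = []
    link_ins = []
    for J in jitters:
        if J < 0:
            width = -int(J)
            start = int(rng.integers(0, K - width + 1))
            link_del.append((start, width))
            link_ins.append(None)
        elif J > 0:
            slot = K // 2 if spec.insert_placement == "center" else int(rng.integers(1, K))
            link_ins.append((slot, int(J)))
            link_del.append(None)
        else:
            link_del.append(None)
            link_ins.append(None)

    # 4. insert residues (background draws, per sequence)
    ins_residues = []
    for i in range(n):
        k = (var_ins[i][1] if var_ins[i] else 0) + (link_ins[i][1] if link_ins[i] else 0)
        ins_residues.append(rng.choice(N_AA, size=k, p=q) if k else np.empty(0, dtype=int))

    # 5. parent offsets for provenance spans
    offsets = rng.integers(1, 200, size=n)

    # assemble rows / sequences / truth
    var_slot_max: dict[int, int] = {}
    link_slot_max: dict[int, int] = {}
    for i in range(n):
        if var_ins[i]:
            s, c = var_ins[i]
            var_slot_max[s] = max(var_slot_max.get(s, 0), c)
        if link_ins[i]:
            s, c = link_ins[i]
            link_slot_max[s] = max(link_slot_max.get(s, 0), c)

    v0 = b.dna_binding            # match columns before the variable region
    l0 = b.dna_binding + b.variable + b.alpha  # before the linker
    # global insert slots (number of match columns to the left)
    slot_max: dict[int, int] = {}
    for s, c in var_slot_max.items():
        slot_max[v0 + s] = c
    for s, c in link_slot_max.items():
        slot_max[l0 + s] = c
    slots_sorted = sorted(slot_max)

    col_is_match: list[bool] = []
    for mcol in range(total + 1):
        if mcol in slot_max:
            col_is_match.extend([False] * slot_max[mcol])
        if mcol < total:
            col_is_match.append(True)
    # note: slots iterate 0..total; inserts only ever occur at internal slots

    sequences = []
    rows = []
    architecture = []
    letters = np.array(list(AMINO_ACIDS))
    for i in range(n):
        deleted = np.zeros(total, dtype=bool)
        if var_del[i]:
            s, wdt = var_del[i]
            deleted[v0 + s : v0 + s + wdt] = True
        if link_del[i]:
            s, wdt = link_del[i]
            deleted[l0 + s : l0 + s + wdt] = True
        my_ins: dict[int, str] = {}
        used = 0
        if var_ins[i]:
            s, c = var_ins[i]
            my_ins[v0 + s] = "".join(letters[ins_residues[i][:c]]).lower()
            used = c
        if link_ins[i]:
            s, c = link_ins[i]
            my_ins[l0 + s] = "".join(letters[ins_residues[i][used : used + c]]).lower()

        chunks = []
        for mcol in range(total + 1):
            width = slot_max.get(mcol, 0)
            if width:
                run = my_ins.get(mcol, "")
                chunks.append(run + "." * (width - len(run)))
            if mcol < total:
                chunks.append("-" if deleted[mcol] else letters[R[i, mcol]])
        row = "".join(chunks)
        rows.append(row)

        residues = "".join(c.upper() for c in row if c.isalpha())
        off = int(offsets[i])
        seq_id = f"seq{i + 1:04d}"
        sequences.append(
            DomainSequence(seq_id, residues, (off, off + len(residues) - 1))
        )

        L = int(var_lengths[i])
        lk = K + int(jitters[i])
        spans = {}
        pos = 1
        for name, width in (
            ("dna_binding", b.dna_binding),
            ("variable", L),
            ("alpha", b.alpha),
            ("linker", lk),
            ("beta", b.beta),
        ):
            spans[name] = (pos, pos + width - 1)
            pos += width
        architecture.append(spans)

    ids = [s.id for s in sequences]
    true_alignment = MatchAlignment(ids, rows, col_is_match)

    true_identity = {}
    for s in spec.invariant_sites:
        r_idx = AMINO_ACIDS.index(s.residue)
        frac = float(np.mean(R[:, s.column - 1] == r_idx))
        true_identity[(s.column, s.residue)] = frac

    truth = FamilyTruth(
        true_alignment=true_alignment,
        template=spec.template(),
        true_architecture=architecture,
        true_identity=true_identity,
        variable_lengths=var_lengths.astype(int),
        linker_jitters=jitters.astype(int),
    )
    return sequences, truth


def length_sampler_summary(
    spec: SyntheticFamilySpec, n_draws: int, bin_width: int = 20
) -> LengthDistribution:
    """Empirical binned distribution of sampled variable-region lengths.

    A calibration helper: draws from the spec's variable-length sampler (seeded
    from the spec seed on a separate stream) and bins the results.
    """
    if n_draws < 1:
        raise SpecError(f"n_draws must be >= 1, got {n_draws}")
    rng = np.random.default_rng([spec.seed, 1])
    pmf = spec.variable_length_sampler.pmf()
    draws = rng.choice(len(pmf), size=n_draws, p=pmf)
    top = (int(draws.max()) // bin_width + 1) * bin_width
    edges = np.arange(0, top + bin_width, bin_width)
    counts, _ = np.histogram(draws, bins=edges)
    return LengthDistribution(
        region="variable",
        edges=edges,
        counts=counts,
        percentages=100.0 * counts / n_draws,
    )
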