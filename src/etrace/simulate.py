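"""Synthetic ground-truth data for the divergence scan and kinetics chain.

Two generators:

* :func:`simulate_grouped_msa` builds a pooled two-group protein
  alignment with a conserved core shared by both groups, a fraction of
  near-uniform variable columns, i.i.d. gaps, and "planted" sites where
  the two groups prefer different residues at known frequencies. The
  defaults emulate a 27-vs-24 ortholog comparison with planted modal
  frequencies 0.82 and 0.99, the regime in which specificity-determining
  positions are typically reported.

* :func:`simulate_kinetic_traces` builds absorbance time courses from
  Michaelis-Menten velocities using a linear early-phase model (the
  pipeline only consumes initial slopes), truncated so that no more
  substrate is consumed than was supplied, with optional Gaussian
  instrument noise.

Both are fully reproducible from their seed, and both can write the
exact on-disk formats the pipeline consumes so end-to-end tests run
through the public interface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import SimulationConfigError
from .kinetics import KineticTrace, michaelis_menten, write_trace
from .seqio import (
    AMINO_ACIDS,
    Alignment,
    GroupedAlignment,
    Sequence,
    write_fasta,
    write_groups,
)

N_AA = len(AMINO_ACIDS)
_AA_ARRAY = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)


@dataclass
class PlantedSite:
    """One group-differentiating column: modal residue + frequency per group."""

    column: int  # 1-based
    modal_a: str
    modal_b: str
    freq_a: float = 0.82
    freq_b: float = 0.99


@dataclass
class MSASimConfig:
    """Parameters of the synthetic two-group alignment.

    Defaults mirror a 27-ortholog vs 24-ortholog comparison over 300
    columns with a strongly conserved shared core (each sequence carries
    a column's consensus with probability 0.9), 10% near-uniform
    variable columns, and 2% i.i.d. gaps.
    """

    n_a: int = 27
    n_b: int = 24
    length: int = 300
    planted_sites: list[PlantedSite] = field(default_factory=list)
    background_conservation: float = 0.9
    variable_fraction: float = 0.1
    gap_rate: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.n_a < 2 or self.n_b < 2:
            raise SimulationConfigError("n_a and n_b must each be >= 2")
        if self.length < 1:
            raise SimulationConfigError("length must be >= 1")
        cols = [p.column for p in self.planted_sites]
        if len(set(cols)) != len(cols):
            raise SimulationConfigError("planted_sites: columns must be distinct")
        for p in self.planted_sites:
            if not 1 <= p.column <= self.length:
                raise SimulationConfigError(
                    f"planted_sites: column {p.column} outside 1..{self.length}"
                )
            for nm, f in (("freq_a", p.freq_a), ("freq_b", p.freq_b)):
                if not 0 < f <= 1:
                    raise SimulationConfigError(
                        f"planted_sites: {nm} must be in (0, 1], got {f}"
                    )
            for nm, r in (("modal_a", p.modal_a), ("modal_b", p.modal_b)):
                if r not in AMINO_ACIDS:
                    raise SimulationConfigError(
                        f"planted_sites: {nm} must be a standard amino acid, got {r!r}"
                    )
        for nm, v in (
            ("background_conservation", self.background_conservation),
            ("variable_fraction", self.variable_fraction),
            ("gap_rate", self.gap_rate),
        ):
            if not 0 <= v <= 1:
                raise SimulationConfigError(f"{nm} must be in [0, 1], got {v}")


def _fill_modal(rng, n, modal_idx, freq):
    """Residue indices: `modal_idx` with prob `freq`, else a random other."""
    out = np.full(n, modal_idx, dtype=np.int64)
    off = rng.random(n) >= freq
    k = int(off.sum())
    if k:
        others = rng.integers(0, N_AA - 1, size=k)
        others[others >= modal_idx] += 1  # skip the modal residue
        out[off] = others
    return out


def simulate_grouped_msa(
    cfg: MSASimConfig,
) -> tuple[GroupedAlignment, list[tuple[int, str, str]]]:
    """Generate a grouped alignment plus its planted-site ground truth.

    Returns the GroupedAlignment (references = first sequence of each
    group, kept gap-free at planted columns) and a list of
    (column, modal_a, modal_b) tuples for the planted sites.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_a + cfg.n_b
    L = cfg.length
    planted_cols = {p.column for p in cfg.planted_sites}

    # choose variable columns among the non-planted ones
    free = np.array([c for c in range(1, L + 1) if c not in planted_cols])
    n_var = int(round(cfg.variable_fraction * L))
    n_var = min(n_var, len(free))
    variable_cols = set(rng.choice(free, size=n_var, replace=False)) if n_var else set()

    mat = np.empty((n, L), dtype=np.int64)
    for c in range(1, L + 1):
        j = c - 1
        if c in planted_cols:
            p = next(ps for ps in cfg.planted_sites if ps.column == c)
            ia, ib = AMINO_ACIDS.index(p.modal_a), AMINO_ACIDS.index(p.modal_b)
            mat[: cfg.n_a, j] = _fill_modal(rng, cfg.n_a, ia, p.freq_a)
            mat[cfg.n_a :, j] = _fill_modal(rng, cfg.n_b, ib, p.freq_b)
        elif c in variable_cols:
            mat[:, j] = rng.integers(0, N_AA, size=n)
        else:
            consensus = int(rng.integers(0, N_AA))
            mat[:, j] = _fill_modal(rng, n, consensus, cfg.background_conservation)

    gaps = rng.random((n, L)) < cfg.gap_rate
    # the two reference rows (first of each group) stay gap-free at
    # planted columns so coordinates there are always reportable
    for c in planted_cols:
        gaps[0, c - 1] = False
        gaps[cfg.n_a, c - 1] = False

    letters = _AA_ARRAY[mat]
    letters[gaps] = ord("-")
    rows = [bytes(row).decode() for row in letters]

    seqs, group_of = [], {}
    for i in range(cfg.n_a):
        sid = f"grpA_{i + 1:02d}"
        seqs.append(Sequence(id=sid, residues=rows[i], description="group A ortholog"))
        group_of[sid] = "A"
    for i in range(cfg.n_b):
        sid = f"grpB_{i + 1:02d}"
        seqs.append(
            Sequence(id=sid, residues=rows[cfg.n_a + i], description="group B ortholog")
        )
        group_of[sid] = "B"
    ga = GroupedAlignment(
        alignment=Alignment(seqs),
        group_of=group_of,
        ref_a="grpA_01",
        ref_b="grpB_01",
    )
    truth = [(p.column, p.modal_a, p.modal_b) for p in cfg.planted_sites]
    return ga, truth


def write_msa_dataset(ga: GroupedAlignment, truth, outdir) -> dict[str, Path]:
    """Write aligned FASTA + group TSV + ground-truth JSON to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "msa": outdir / "alignment.fasta",
        "groups": outdir / "groups.tsv",
        "truth": outdir / "truth.json",
    }
    write_fasta(ga.alignment, paths["msa"])
    write_groups(ga.group_of, paths["groups"])
    paths["truth"].write_text(
        json.dumps(
            {
                "planted_sites": [
                    {"column": c, "modal_a": a, "modal_b": b} for c, a, b in truth
                ],
                "ref_a": ga.ref_a,
                "ref_b": ga.ref_b,
            },
            indent=1,
        )
    )
    return paths


# ---------------------------------------------------------------------------
# Kinetic traces


@dataclass
class KineticsSimConfig:
    """Parameters of the synthetic absorbance assay.

    The default conversion factor 1e-4 M/AU corresponds to an extinction
    coefficient of 1e4 /M/cm at 1 cm path length (the order of magnitude
    of phenylglyoxal at 250 nm); substrate consumption lowers the signal
    by default, as in a consumption assay.
    """

    vmax: float  # M/s
    km: float  # M
    enzyme_conc: float  # M
    substrate_levels: list[float]  # M
    duration_s: float = 300.0
    n_timepoints: int = 30
    noise_sd: float = 0.0  # absorbance units
    conversion: float = 1e-4  # M per AU
    direction: str = "decrease"
    baseline: Optional[float] = None  # AU; default derived from direction
    replicates: int = 1
    seed: int = 0

    def validate(self) -> None:
        for nm in ("vmax", "km", "enzyme_conc", "duration_s", "conversion"):
            if getattr(self, nm) <= 0:
                raise SimulationConfigError(f"{nm} must be > 0, got {getattr(self, nm)}")
        if self.n_timepoints < 3:
            raise SimulationConfigError("n_timepoints must be >= 3")
        if self.noise_sd < 0:
            raise SimulationConfigError("noise_sd must be >= 0")
        if self.replicates < 1:
            raise SimulationConfigError("replicates must be >= 1")
        if not self.substrate_levels:
            raise SimulationConfigError("substrate_levels must be non-empty")
        if any(s <= 0 for s in self.substrate_levels):
            raise SimulationConfigError("substrate_levels must all be > 0")
        if len(set(self.substrate_levels)) != len(self.substrate_levels):
            raise SimulationConfigError("substrate_levels must be distinct")
        if self.direction not in ("increase", "decrease"):
            raise SimulationConfigError(f"unknown direction {self.direction!r}")


def simulate_kinetic_traces(
    cfg: KineticsSimConfig, label: str = "sim"
) -> list[KineticTrace]:
    """Simulate one trace per (substrate level, replicate).

    signal(t) = baseline +/- min(v t, S) / conversion + noise, with
    v = Vmax S / (Km + S); the truncation keeps consumed substrate <= S.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    times = np.linspace(0.0, cfg.duration_s, cfg.n_timepoints)
    sign = 1.0 if cfg.direction == "increase" else -1.0
    traces = []
    for rep in range(cfg.replicates):
        for s_conc in cfg.substrate_levels:
            v = float(michaelis_menten(s_conc, cfg.vmax, cfg.km))
            consumed = np.minimum(v * times, s_conc)
            if cfg.baseline is not None:
                baseline = cfg.baseline
            elif cfg.direction == "decrease":
                baseline = s_conc / cfg.conversion  # start at the substrate's A
            else:
                baseline = 0.05
            signal = baseline + sign * consumed / cfg.conversion
            if cfg.noise_sd > 0:
                signal = signal + rng.normal(0.0, cfg.noise_sd, size=times.shape)
            traces.append(
                KineticTrace(
                    times=times,
                    signal=signal,
                    substrate_conc=s_conc,
                    enzyme_conc=cfg.enzyme_conc,
                    conversion=cfg.conversion,
                    direction=cfg.direction,  # type: ignore[arg-type]
                    label=label,
                    replicate=rep,
                )
            )
    return traces


def design_substrate_levels(km: float, lo: float = 0.2, hi: float = 5.0, n: int = 8):
    """Log-spaced substrate grid spanning lo..hi multiples of Km."""
    return list(np.geomspace(lo * km, hi * km, n))


def safe_duration(cfg_vmax: float, km: float, s_min: float, consumed_frac: float = 0.2):
    """Duration keeping consumption <= `consumed_frac` of S at the lowest level,
    so the early phase stays linear at every level of the design."""
    v_min = cfg_vmax * s_min / (km + s_min)
    return consumed_frac * s_min / v_min


def write_trace_dataset(traces, outdir) -> list[Path]:
    """Write each trace as CSV + JSON sidecar into a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, tr in enumerate(traces):
        p = outdir / f"trace_{i:03d}.csv"
        write_trace(tr, p)
        paths.append(p)
    return paths
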