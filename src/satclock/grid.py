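"""The 45-run sensitivity grid: one config per comparative dating run.

Each run varies one ingredient at a time from the reference analysis
(run 3: seven nuclear loci, eight outgroup taxa, six fossil constraints):
locus panel (including a mitochondrial partition or nothing but it), ingroup
and outgroup taxon sampling, the subset / temporal placement of fossil
constraints, and the prior shape.  Counts and comments follow the published
run table; the mapping onto the packaged fixture's loci, taxa and
calibrations is deterministic.

Conventions for realizing the counts:

* k outgroups = the first k entries of :data:`satclock.trees.OUTGROUP_PRIORITY`
  (grebes first, then the taxa carrying the standard six constraints, then
  anhinga, cormorant, tropicbird).
* 4/5/6 nuclear loci = the first 4/5/6 of the seven-locus nuclear panel;
  the six "1 locus excluded" runs drop the 1st..6th nuclear locus in turn.
* "youngest constraints only" = crown Podicipedidae + crown Mirandornithes;
  "oldest constraints only" = the standard six minus those two.
* runs whose original meaning is Bayesian-only (joint-prior tests,
  unpartitioned likelihood, prior-shape variants) map to the nearest proxy
  and are flagged ``approximate``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

from . import calibrations as cal_mod
from . import simulate as sim_mod
from . import trees

__all__ = ["RunConfig", "make_run_grid", "REFERENCE_RUN_ID"]

REFERENCE_RUN_ID = 3

_NUC = [l.name for l in sim_mod.DEFAULT_NUCLEAR_LOCI]
_MT = sim_mod.DEFAULT_MTDNA_LOCUS.name

_SIX = [c.label for c in cal_mod.STANDARD_SIX]
_YOUNG2 = [c.label for c in cal_mod.YOUNGEST_TWO]
_OLD4 = [l for l in _SIX if l not in _YOUNG2]
_ANHINGA = "stem_Anhingidae"
_PHOE = "crown_Phoenicopteridae"

# labels of the four individually added/removed deep constraints
_PENGUIN = "divergence_Sphenisciformes_Procellariiformes"
_FRIGATE = "stem_Fregatidae"
_GANNET = "stem_Sulidae"
_PELICAN = "stem_Pelecanidae"


@dataclass(frozen=True)
class RunConfig:
    """One cell of the sensitivity grid."""

    run_id: int
    loci: tuple
    n_outgroups: int
    flamingos: tuple
    calibrations: tuple  # calibration labels
    note: str
    prior_mode: str = "point_min"  # point_min | soft
    shape_override: Optional[str] = None  # uniform | lognormal_wide | lognormal_max
    pooled_loci: bool = False  # proxy for "loci unpartitioned"
    approximate: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.loci:
            raise ValueError(f"run {self.run_id}: empty locus set")
        if not self.flamingos:
            raise ValueError(f"run {self.run_id}: empty ingroup")

    @property
    def taxa(self) -> tuple:
        exclude_grebes = "grebe" in self.note and "excluded" in self.note
        pool = [t for t in trees.OUTGROUP_PRIORITY if not (exclude_grebes and t in trees.GREBES)]
        return tuple(self.flamingos) + tuple(pool[: self.n_outgroups])

    @property
    def dated(self) -> bool:
        return len(self.calibrations) > 0

    def calibration_priors(self) -> tuple:
        priors = tuple(cal_mod.calibration_by_label(l) for l in self.calibrations)
        if self.shape_override == "uniform":
            priors = tuple(c.with_shape("uniform", soft_max=_max_age(c)) for c in priors)
        elif self.shape_override in ("lognormal_wide", "lognormal_max"):
            priors = tuple(c.with_shape("lognormal", soft_max=_max_age(c)) for c in priors)
        return priors

    def to_dict(self) -> dict:
        return {
            "run_id": self.run_id,
            "n_loci": len(self.loci),
            "loci": list(self.loci),
            "n_outgroups": self.n_outgroups,
            "taxa": list(self.taxa),
            "n_constraints": len(self.calibrations),
            "calibrations": list(self.calibrations),
            "prior_mode": self.prior_mode,
            "shape_override": self.shape_override,
            "pooled_loci": self.pooled_loci,
            "approximate": self.approximate,
            "note": self.note,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            run_id=d["run_id"],
            loci=tuple(d["loci"]),
            n_outgroups=d["n_outgroups"],
            flamingos=tuple(t for t in d["taxa"] if t in trees.FLAMINGOS),
            calibrations=tuple(d["calibrations"]),
            note=d["note"],
            prior_mode=d.get("prior_mode", "point_min"),
            shape_override=d.get("shape_override"),
            pooled_loci=d.get("pooled_loci", False),
            approximate=d.get("approximate", False),
            seed=d.get("seed", 0),
        )


def _max_age(c: cal_mod.CalibrationPrior) -> float:
    # soft maxima from the absence of older fossils: 30 MY for the grebe
    # crown (Eocene-Oligocene boundary), 65 MY (K-T boundary) otherwise
    return 30.0 if c.label == "crown_Podicipedidae" else 65.0


def _run(
    run_id, loci, n_out, cals, note, flamingos=trees.FLAMINGOS, **kw
) -> RunConfig:
    return RunConfig(
        run_id=run_id,
        loci=tuple(loci),
        n_outgroups=n_out,
        flamingos=tuple(flamingos),
        calibrations=tuple(cals),
        note=note,
        **kw,
    )


def make_run_grid(base_seed: int = 0) -> list[RunConfig]:
    """All 45 run configurations; run 3 is the nDNA reference."""
    two_flam = ("Phoenicoparrus_andinus", "Phoenicopterus_chilensis")  # one per genus
    g: list[RunConfig] = [
        _run(1, _NUC, 8, [], "Testing joint prior", approximate=True),
        _run(2, _NUC[:4], 10, [], "Testing joint prior", approximate=True),
        _run(3, _NUC, 8, _SIX, "Reference run nDNA"),
        _run(4, _NUC + [_MT], 8, _SIX, "See 3, +mtDNA"),
        _run(5, [_MT], 8, _SIX, "mtDNA only"),
        _run(6, _NUC, 8, _SIX, "See 3, 4 of 6 flamingo species excluded", flamingos=two_flam),
        _run(7, _NUC[:4], 10, _SIX, "See 3, 4 loci only"),
        _run(8, _NUC[:4], 10, _SIX + [_ANHINGA], "See 7, anhinga constraint added"),
        _run(9, _NUC[:5], 9, _SIX, "See 3, 5 loci only"),
        _run(10, _NUC[:5], 9, _SIX + [_ANHINGA], "See 9, anhinga constraint added"),
        _run(11, _NUC[:6], 8, _SIX, "See 3, 6 loci only"),
        _run(12, _NUC[:4], 10, _YOUNG2, "See 7, youngest constraints only"),
        _run(13, _NUC[:5], 9, _YOUNG2, "See 9, youngest constraints only"),
        _run(14, _NUC[:6], 8, _YOUNG2, "See 11, youngest constraints only"),
        _run(15, _NUC, 8, _YOUNG2, "See 3, youngest constraints only"),
        _run(16, _NUC[:4], 3, _YOUNG2, "See 12, reduced outgroup sampling"),
        _run(17, _NUC[:5], 3, _YOUNG2, "See 13, reduced outgroup sampling"),
        _run(18, _NUC[:6], 3, _YOUNG2, "See 14, reduced outgroup sampling"),
        _run(19, _NUC, 3, _YOUNG2, "See 15, reduced outgroup sampling"),
    ]
    for i in range(6):  # runs 20-25: drop one nuclear locus in turn
        kept = [l for j, l in enumerate(_NUC) if j != i]
        g.append(_run(20 + i, kept, 8, _SIX, f"See 3, 1 locus excluded ({_NUC[i]})"))
    g += [
        _run(26, _NUC, 8, _SIX, "See 3, constraint maxima increased to 65 or 30",
             prior_mode="soft", shape_override="lognormal_max", approximate=True),
        _run(27, _NUC, 8, _SIX, "See 26, uniform prior distribution",
             prior_mode="soft", shape_override="uniform", approximate=True),
        _run(28, _NUC, 8, _SIX, "See 26, 95% prior range at 65 or 30",
             prior_mode="soft", shape_override="lognormal_wide", approximate=True),
        _run(29, _NUC, 8, _SIX, "See 3, loci unpartitioned",
             pooled_loci=True, approximate=True),
        _run(30, _NUC, 8, _SIX + [_PHOE], "See 3, + min Phoenicopteridae = 5.33 constraint"),
        _run(31, _NUC, 8, _YOUNG2 + [_PHOE], "See 15, + min Phoenicopteridae = 5.33 constraint"),
        _run(32, _NUC, 8, _OLD4, "See 3, sistergroup (grebe) taxa excluded"),
        _run(33, _NUC, 8, [l for l in _SIX if l != _PENGUIN], "See 3, stem penguin constraint excluded"),
        _run(34, _NUC, 8, [l for l in _SIX if l != _FRIGATE], "See 3, stem fregatebird constraint excluded"),
        _run(35, _NUC, 8, [l for l in _SIX if l != _GANNET], "See 3, stem gannet constraint excluded"),
        _run(36, _NUC, 8, [l for l in _SIX if l != _PELICAN], "See 3, stem pelican constraint excluded"),
        _run(37, _NUC, 8, _OLD4, "See 3, oldest constraints only"),
        _run(38, _NUC, 8, _YOUNG2 + [_PENGUIN], "See 15, stem penguin constraint added"),
        _run(39, _NUC, 8, _YOUNG2 + [_FRIGATE], "See 15, stem fregatebird constraint added"),
        _run(40, _NUC, 8, _YOUNG2 + [_GANNET], "See 15, stem gannet constraint added"),
        _run(41, _NUC, 8, _YOUNG2 + [_PELICAN], "See 15, stem pelican constraint added"),
        _run(42, _NUC, 8, [_PENGUIN], "See 3, stem penguin constraint only"),
        _run(43, _NUC, 8, [_FRIGATE], "See 3, stem fregatebird constraint only"),
        _run(44, _NUC, 8, [_GANNET], "See 3, stem gannet constraint only"),
        _run(45, _NUC, 8, [_PELICAN], "See 3, stem pelican constraint only"),
    ]
    g = [replace(r, seed=base_seed + r.run_id) for r in g]
    assert [r.run_id for r in g] == list(range(1, 46))
    return g
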