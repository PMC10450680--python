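"""Shared study conditions and paths for the numbered analysis scripts.

Three measurement campaigns, mirroring the questions the pipeline answers:

* enkephalin diastereomers (single d-amino-acid substitution) in a
  CytK-K128F-like pore — cluster resolution of nearly identical peptides;
* a cyclized/linear lanthipeptide pair (RiPep2-like constitutional isomers)
  in a FraC-G13F-like pore — resolution plus capture-bias-corrected
  quantification of the extent of cyclization;
* a SyncA2-like pair where the cyclized form shows large two-level current
  fluctuations — logistic classification on (I_ex%, dwell, sigma_b).

Dwell means and capture rates are not published for these peptides; values
here are chosen for realistic single-channel kinetics (ms-scale dwells,
a few to tens of captures per second) and adequate event counts, with
occupancy well below the single-molecule limit.
"""

from pathlib import Path

from nanopept import SimConfig, SpeciesParams

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"

OPEN_CURRENT = 100.0  # pA
OPEN_NOISE_SD = 2.0  # pA, pre-filter


def _cfg(species, duration, seed):
    return SimConfig(
        open_current=OPEN_CURRENT,
        open_noise_sd=OPEN_NOISE_SD,
        duration=duration,
        species=tuple(species),
        seed=seed,
    )


# --- enkephalin diastereomers (CytK-K128F-like, shallow blockades) ---------
L_ENK = SpeciesParams("YGGFL", iex_mean=24.5, iex_sd=1.1, dwell_mean=5.0,
                      sigma_b=1.0, capture_rate=15.0)
D_LEU5 = SpeciesParams("YGGFdL", iex_mean=26.3, iex_sd=0.9, dwell_mean=5.0,
                       sigma_b=1.0, capture_rate=15.0)

# --- lanthipeptide constitutional isomers (FraC-G13F-like, deep) -----------
RIPEP2 = SpeciesParams("RiPep2", iex_mean=84.2, iex_sd=1.4, dwell_mean=100.0,
                       sigma_b=2.0, capture_rate=7.0)
RIPEP2_DHB = SpeciesParams("RiPep2-Dhb", iex_mean=79.6, iex_sd=1.5,
                           dwell_mean=100.0, sigma_b=2.0, capture_rate=7.0)
# true extent of cyclization and capture bias used in the quantification demo
TRUE_CONVERSION = 71.0
CAPTURE_BIAS_F = 2.0

# --- SyncA2-like pair: cyclized form fluctuates between two sub-levels -----
SYNCA2 = SpeciesParams("SyncA2", iex_mean=72.0, iex_sd=2.5, dwell_mean=8.0,
                       sigma_b=2.0, capture_rate=15.0,
                       fluctuation_mode="two_level", two_level_split=6.0,
                       two_level_rate=0.5)
SYNCA2_L = SpeciesParams("SyncA2-L", iex_mean=76.0, iex_sd=2.0, dwell_mean=8.0,
                         sigma_b=1.0, capture_rate=15.0)


def _scaled(sp: SpeciesParams, rate: float, dwell: float | None = None) -> SpeciesParams:
    from dataclasses import replace

    if dwell is None:
        return replace(sp, capture_rate=rate)
    return replace(sp, capture_rate=rate, dwell_mean=dwell)


def recordings(seed: int = 1) -> dict[str, SimConfig]:
    """All simulated measurements of the study, keyed by recording name."""
    c, f = TRUE_CONVERSION, CAPTURE_BIAS_F
    base = 12.0
    quant_dwell = 20.0
    return {
        # single-peptide calibrations + mixture, enkephalins
        "enk_l": _cfg([L_ENK], 20.0, seed + 11),
        "enk_d": _cfg([D_LEU5], 20.0, seed + 12),
        "enk_mix": _cfg([_scaled(L_ENK, 8.0), _scaled(D_LEU5, 8.0)], 20.0, seed + 13),
        # lanthipeptide singles (long recordings: cluster statistics)
        "ripep_cyc": _cfg([RIPEP2], 60.0, seed + 21),
        "ripep_lin": _cfg([RIPEP2_DHB], 60.0, seed + 22),
        # quantification: modified sample (c% cyclized, bias F) + equimolar mix
        "ripep_sample": _cfg(
            [
                _scaled(RIPEP2, c / 100 * f * base, quant_dwell),
                _scaled(RIPEP2_DHB, (100 - c) / 100 * base, quant_dwell),
            ],
            60.0,
            seed + 23,
        ),
        "ripep_mix": _cfg(
            [
                _scaled(RIPEP2, 0.5 * f * base, quant_dwell),
                _scaled(RIPEP2_DHB, 0.5 * base, quant_dwell),
            ],
            60.0,
            seed + 24,
        ),
        # SyncA2 classification set
        "synca2": _cfg([SYNCA2], 20.0, seed + 31),
        "synca2_l": _cfg([SYNCA2_L], 20.0, seed + 32),
        "synca2_mix": _cfg([_scaled(SYNCA2, 8.0), _scaled(SYNCA2_L, 8.0)], 20.0, seed + 33),
    }


def trace_prefix(name: str) -> Path:
    return SCRATCH / "recordings" / name


def events_path(name: str) -> Path:
    return SCRATCH / "events" / f"{name}.events.tsv"


def truth_path(name: str) -> Path:
    return SCRATCH / "recordings" / f"{name}.truth.tsv"
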