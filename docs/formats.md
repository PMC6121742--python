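# File formats

All formats are plain text except the optional HDF5 photon container.
Separator is inferred from the extension: `.tsv`/`.txt` are
tab-separated, everything else comma-separated.

## Photon streams (confocal)

CSV/TSV with a header row and one photon per line:

    timestamp_s,channel,slot
    0.0001937,Dem,Dex
    0.0002141,Aem,Dex
    0.0002380,Aem,Aex

* `timestamp_s` — arrival time in seconds (float64); rows need not be
  sorted, readers sort stably.
* `channel` — `Dem` (donor emission) or `Aem` (acceptor emission).
* `slot` — excitation slot at arrival: `Dex` or `Aex`.

HDF5 dialect: group `/photons` with datasets `timestamps` (float64,
seconds), `channel` and `slot` (uint8; 0 = Dem/Dex, 1 = Aem/Aex), and
attributes `channel_codes`, `slot_codes`, `time_unit` spelling the codes
out.

## Trace tables (TIRF)

Long-format CSV/TSV, one frame per row, grouped by molecule:

    trace_id,frame,I_DemDex,I_AemDex,I_AemAex,x,y

* `frame` — 0-based frame index; `x`, `y` — spot position in pixels
  (constant within a trace).
* Intensities are camera counts per frame for the three channel/slot
  combinations.

## Spectra

Two-column CSV `(wavelength_nm, value)`, `#` comments allowed.  Donor
emission in arbitrary units (normalized internally); acceptor extinction
either absolute in M⁻¹ cm⁻¹ or rescaled to a supplied maximum.

## Accessible-volume clouds

XYZ-style whitespace text, one point per line: `x y z weight` (Å; weight
optional, uniform if absent).  Obstacle sets: CSV with columns
`x, y, z, radius` in Å.

## Conventions

Coordinates are right-handed in Å with no implicit origin.  Frame indices
are 0-based; time intervals are half-open `[start, stop)`.  Run
configurations are YAML files whose keys mirror
`fretkit.pipeline.DEFAULT_CONFIG`; summary reports are JSON; per-event
tables are TSV.  Simulation ground truth is written as a `.truth.json`
sidecar next to the data file.
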