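# echolayers

Echo-integration and long-term trend analysis for pelagic acoustic surveys,
aimed at upwelling-shelf ecosystems: how stable are plankton and pelagic-fish
abundance, their spatial centres of gravity, and their diel vertical
migration (DVM) behaviour under a changing environment?

The package processes gridded volume-backscatter echograms the way a
fisheries-acoustics lab would, and couples the acoustic series to monthly
satellite-style environmental series (SST, upwelling-favourable wind,
surface chlorophyll-a) through a shared climatology/anomaly/rank-trend
toolkit. Because real cruise acoustics are rarely public, a first-class
synthetic-data module generates surveys with known ground truth — migrating
scattering layers, fish schools, seasonal environmental cycles with
configurable trends — so every stage of the pipeline is testable end to end.

## The method

**Echo-integration.** Volume backscattering strength `Sv` (dB re 1 m⁻¹) on a
depth × along-track grid is integrated per elementary sampling distance unit
(ESDU, 0.1 nmi) into the Nautical Area Scattering Coefficient

    NASC = 4π · 1852² · Σ_z 10^(Sv/10) · Δz   [m² nmi⁻²],

with a 10 m surface offset and exclusion of cells below the seabed, keeping
only continental-shelf ESDUs (bottom depth 10–150 m). NASC is the relative
abundance proxy ("PA") throughout.

**Trophic classification.** Backscatter is split by half-open dB bands into
a plankton group PG `[−80, −65)`, a pelagic-fish group PFG `[−65, −20)` and
the total TG `[−80, −20)` before integration, so `NASC_TG = NASC_PG +
NASC_PFG` holds exactly.

**Diel analysis.** ESDUs are labelled day/night by geometric solar altitude
(day above +18°, night below −18°); twilight ESDUs are discarded. Per 1-m
depth bin, `Δ_DVM = mean night PA − mean day PA` localises migration, and a
paired Wilcoxon signed-rank test on annual day/night mean PA tests the diel
contrast.

**Spatial displacement.** The yearly centre of gravity of each group is the
NASC-weighted mean position, `lat_a = Σᵢ wᵢ·latᵢ / Σᵢ wᵢ` (likewise for
longitude), computed separately north and south of Cap Blanc (20.77°N).
Interannual displacement is tested per coordinate with Spearman's rank
correlation against time, exact by permutation for n ≤ 9.

**Environment.** Monthly series are deseasonalised by subtracting the
calendar-month climatology; anomalies (and annual acoustic means) feed the
same Spearman trend test. A 13-term annual smoother (end weights 1/24) is
provided for display.

## Worked example

The numbered drivers under `analysis/` run the full story; `analysis/06_full_pipeline.py`
reproduces the consolidated 13-survey-year report:

```
$ python analysis/06_full_pipeline.py
report 27e618944b00f2d1: 5023 ESDUs, 13 survey years
  north: PG=27.0, PFG=329.7, TG=356.7 m^2 nmi^-2
  south: PG=33.8, PFG=407.7, TG=441.5 m^2 nmi^-2
  PG:PFG ratio = 0.082
significant trends (7 of 24 tests):
  environment: north SST rho=+0.95, p=2.43e-10
  ...
```

Read: plankton carries about one tenth of the fish group's acoustic
abundance, the south area is richer than the north, the simulated warming
and wind trends are detected in every area, and — as expected for a
stationary community — no acoustic abundance trend emerges. The DVM driver
(`analysis/03_diel_migration.py`) recovers the migrating plankton layer:

```
PG: delta_DVM peak at 14 m, Wilcoxon annual day/night W=0, p=0.000244
PFG: delta_DVM peak at 35 m, Wilcoxon annual day/night W=27, p=0.216
```

The layer simulated at 15 m by night produces its positive `Δ_DVM` peak at
14 m and a decisive day/night contrast; the non-migrating fish school shows
neither. A `echolayers` CLI (`simulate`, `integrate`, `diel`, `barycenter`,
`trends`, `run-all`, `validate`) wraps the same library for shell use.

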