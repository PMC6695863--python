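# npzdvar

A nitrogen-based NPZD (nutrient–phytoplankton–zooplankton–detritus) marine
ecosystem model for an idealized Bohai Sea domain, with adjoint-based
variational assimilation of surface phytoplankton observations.  The control
field (the initial surface phytoplankton distribution) is reduced to a sparse
set of *independent points* and expanded to the full grid by a fixed linear
operator built from either a bicubic **spline interpolation (SI)** or
**Cressman interpolation (CI)**, so the two interpolators can be compared in
identical twin experiments.

## What is inside

| module | contents |
| --- | --- |
| `npzdvar.grid` | model domain (37–41°N, 117.5–122.5°E, 4′ cells, six z-layers), idealized three-bay bathymetry, synthetic gyre/SST/irradiance forcing, prescribed truth fields (paraboloid "IE1", temperature-driven "IE2") |
| `npzdvar.model` | NPZD biology (Michaelis–Menten uptake, Steele light response, Ivlev grazing, Q10 temperature factors), finite-volume upwind transport with sinking, operator-split forward integration |
| `npzdvar.adjoint` | cost function, exact discrete adjoint of the forward step, gradient projection onto independent points, steepest-descent assimilation loop |
| `npzdvar.ips` | independent-point selection, spline/Cressman weight matrices, field expansion, interpolation accuracy/smoothness demo |
| `npzdvar.metrics` | NCF, MAE, RMSE, similarity coefficient; chlorophyll-a → carbon → nitrogen conversions |
| `npzdvar.config` / `io` / `experiment` / `cli` | YAML run configuration, NetCDF/CSV/JSON output, twin-experiment driver, command line |

Everything runs offline: forcing and truth fields are generated
parametrically (externally supplied NetCDF fields can be substituted), and
NetCDF I/O uses the SciPy backend, so no netCDF4 library is required.

## Command line

All subcommands accept `--config <yaml>`, `--seed <int>` and `--output <dir>`:

```sh
npzdvar forward --truth IE1                 # free forward run, writes trajectory
npzdvar twin --truth IE1 --method spline    # twin experiment + metrics JSON
npzdvar twin --truth IE2 --method cressman
npzdvar assimilate --obs-file obs.nc        # assimilate external observations
npzdvar interp-demo --spacing 5             # SI vs CI accuracy/smoothness report
npzdvar metrics model.nc obs.nc --variable P
```

A configuration file only needs the keys you want to change, e.g.

```yaml
model:
  Vm: 1.2          # phytoplankton maximum growth rate, 1/day
ips:
  method: cressman
  spacing: 5
assimilation:
  max_iterations: 100
seed: 7
```

Unknown keys are rejected by name.  Every run writes a provenance record
(config hash, seed, package version) next to its outputs.

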