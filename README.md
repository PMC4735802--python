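# channelpore

Structural validation of open-pore dimensions in potassium-channel models.

The package measures the **effective pore radius** `r_E` of a channel
structure — the radius of the largest rigid spherical probe able to enter
the pore from the cytosolic side, at 0.1 Å resolution — and combines it
with the electrophysiological **radius of capture** `r_C` (inferred from
diffusion-limited unitary currents via the hemispheric-sink law
`i_DL = 2π z e₀ c D r_C`) to estimate the hydrated-ion radius
`r_K = r_E − r_C`.

## Method

1. **structure_model** — read PDB (plain or gzipped), keep/strip hetero
   records, assign van der Waals radii (Bondi 1964 default, AMBER
   united-atom selectable), and align the pore axis onto +z with the
   cytosolic side at low z (4-fold symmetry axis, principal axis, or a
   manual anchor pair). The selectivity filter is located from the
   T-V-G-Y-G/T-V-G-F-G signature (or retained K⁺ ions) to set orientation
   and the inner-cavity target.
2. **accessibility** — build a cubic clearance field
   `c(x) = min_i(‖x − x_i‖ − r_i)` (default 0.25 Å spacing, allowed
   0.2–0.5 Å), confined laterally to a 15 Å cylinder about the axis so the
   flood fill cannot detour around the protein exterior. A probe of
   radius r passes iff a 26-connected component of lattice points with
   `c ≥ r` joins the cytosolic boundary slab to a 1 Å axis sphere placed
   5 Å cytosolic of the selectivity-filter anchor. A lattice-exact
   widest-path (maximin bottleneck) value is available as a cross-check,
   plus HOLLOW-style export of the reachable cavity as oxygen
   pseudo-atoms.
3. **pore_search** — scan probe radii on an exact 0.1 Å ladder
   (default 1.4–12 Å); `r_E` is the largest passing rung, confirmed
   against the failing rung 0.1 Å above. If even `r_min` fails, the result
   is censored and reported as `<r_min`.
4. **capture_theory** — unit-checked conversions between `i_DL` (pA) and
   `r_C` (Å) at user-facing electrophysiology units (pA, mM, cm²/s, Å),
   `r_O = r_C + r_K`, `r_K = r_E − r_C`, and named presets
   `BK: r_C = 2.2 Å`, `Shaker: r_C = 0.8 Å`.
5. **synthetic_structures** — ring-stack PDB fixtures (cylinder /
   hourglass / closed) with *exact* analytic bottleneck values, used as
   oracles by the whole test suite; no downloads needed.

## CLI

```sh
channelpore fixtures out/fixtures            # synthetic suite + manifest
channelpore pore-radius my_channel.pdb --out-dir out \
    --spacing 0.25 --r-min 1.4 --r-max 12    # r_E scan -> JSON + TSV
channelpore hydrated --r-e 5.9 --preset BK   # r_K = r_E - r_C
channelpore capture --i-dl 2.7 --c 100 --d 2e-6   # i_DL -> r_C
channelpore table a.pdb b.pdb --preset BK --out table.tsv
```

All options can come from a YAML config (`--config run.yaml`, flags
override); every methodological default in effect is echoed into the JSON
provenance block, and reruns with identical inputs are byte-identical.

## Caveats

- The upstream surface programs' parameter sets (probe chemistry, radii)
  are not published alongside the survey; we default to Bondi radii,
  heavy atoms only, heteroatoms stripped, and a ±0.2 Å tolerance on the
  survey regression acknowledges that uncertainty. Switch
  `--radii-set amber_united` to gauge sensitivity.
- "Entering the pore" is operationalized as reaching an axis sphere 5 Å
  below the selectivity-filter anchor; the depth is configurable
  (`target_depth_below_filter`, or `--target-z` for a fully manual
  target).
- Deposited coordinates are used as-is (no symmetry expansion); supply
  the biological assembly when the asymmetric unit is not the tetramer.
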