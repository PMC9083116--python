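# unfoldkit

Analysis toolkit for protein thermal-unfolding trajectories: per-frame
order parameters, 2-D free-energy landscapes by Boltzmann inversion,
residue-motion cross-correlation matrices, and secondary-structure
timelines — together with a synthetic multi-state trajectory generator
that makes every stage verifiable against known ground truth without
running molecular dynamics.

It is written for structural-bioinformatics work of the kind done when
characterising unfolding intermediates of a small protein domain (for
example the TDP-43 N-terminal domain, an α/β fold whose thermal unfolding
across a 300–500 K ladder passes through partially folded intermediates):
the trajectories already exist (as multi-model PDB files), and the job is
to turn them into quantitative descriptors of the unfolding pathway.

## What it computes

Given a trajectory `x_1 … x_T` over a fixed topology:

- **Cα-RMSD(t)** — minimal root-mean-square deviation to a native
  reference after optimal rigid superposition (Kabsch algorithm, SVD with
  reflection correction).
- **Radius of gyration** `Rg = sqrt(Σ m_k |x_k − x̄|² / Σ m_k)` —
  compactness.
- **Fraction of native contacts** `Nc(t)`: the native contact set is every
  heavy-atom pair from residues ≥ 3 apart in sequence with reference
  distance ≤ 4 Å; `Nc(t)` is the fraction of those pairs still within the
  cutoff in frame `t` (1 = native, → 0 on unfolding).
- **SASA** — solvent-accessible surface area by Shrake–Rupley quadrature
  (deterministic golden-spiral sphere points, 1.4 Å probe), total or per
  side chain (e.g. tracking a buried tryptophan's exposure).
- **Intraprotein H-bond count** — backbone N–H···O=C bonds by a geometric
  criterion (N···O ≤ 3.5 Å, D–H···A ≥ 120°, amide H reconstructed when
  the structure has no hydrogens).
- **RMSF per residue** about the iteratively aligned mean structure.
- **Free-energy landscapes** `F(q₁, q₂) = −RT ln P(q₁, q₂)` over any pair
  of order parameters, with empty bins masked (never `−RT ln 0`), the
  surface shifted to `min F = 0`, basin detection (grid-local minima below
  a depth threshold) and basin ΔF — which for well-separated states
  recovers `−RT ln(p₂/p₁)`.
- **DCCM** `C_ij = ⟨Δx_i·Δx_j⟩ / sqrt(⟨|Δx_i|²⟩⟨|Δx_j|²⟩)` over
  configurable trajectory windows (default: first and last 10 %).
- **Secondary structure** per residue per frame via a simplified
  Kabsch–Sander scheme (electrostatic H-bond energy
  `E = 27.888 (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)` kcal/mol, bond below
  −0.5; helices from consecutive n-turns, strands from bridge patterns,
  plus turn/bend assignments).

The `pipeline` module orchestrates all of this over a multi-temperature
ladder and emits plain-text CSV/grid outputs plus a per-temperature
mean ± SD summary table (RMSD and Rg in nm, SASA in nm², Nc as a
fraction).

Because public unfolding studies rarely deposit raw trajectories, the
`synthetic` module generates fixed-topology toy-protein trajectories with
known statistical structure: a deterministic helix+hairpin fold, an
intermediate template (helix unwound, hairpin intact, ~half the native
contacts), a fully extended unfolded template, Markov switching between
templates with prescribed stationary occupancies, and Gaussian coordinate
jitter. Every population, and therefore every expected Nc level, Rg
ordering and basin ΔF, is known exactly — so the analyses are tested by
parameter recovery, not by eyeballing.

## Worked example

```bash
python examples/02_free_energy_landscape.py
```

simulates 50,000 frames switching between the native fold (90 %) and the
unfolded chain (10 %), builds the (Rg, RMSD) free-energy landscape at
300 K and locates its basins:

```
2 basins on the (Rg, RMSD) landscape (4 visited bins of 3600)
  basin at bin (0, 0): F = 0.000 kcal/mol
  basin at bin (59, 59): F = 1.378 kcal/mol
basin ΔF = 1.378 kcal/mol (population prediction −RT ln(0.1/0.9) = 1.310)
```

The measured basin ΔF recovers the free-energy difference implied by the
90/10 populations to within sampling noise. The other examples cover
order-parameter measurement on a mixture trajectory, secondary-structure
and DCCM contrasts between folded and unfolded trajectory windows, and
the full five-temperature pipeline, whose summary table shows mean Nc
falling (≈0.81 → 0.02) and mean Rg rising (≈1.54 → 2.89 nm) with
temperature — the signature of progressive thermal unfolding.

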