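# allosnet

Dynamical network analysis of molecular-dynamics trajectories, built to
quantify how a binder (an antibody fragment, a modulator, a partner
subunit) reshapes the web of correlated residue motions inside a
receptor — the kind of long-range, allosteric coupling that explains why
a molecule binding the *top* of a domain can close a cleft at its
*bottom*.

The pipeline implements the standard dynamical-network recipe end to end:

1. **Contact network.** One node per residue Cα. An edge joins residues
   whose heavy atoms come within **6 Å** of each other in **≥ 75 %** of a
   window's frames (the wider 6 Å cutoff keeps interface contacts that a
   4.5 Å cutoff misses). Each replica is split into windows (two per
   replica by default) so persistence across windows can separate stable
   couplings from transients.
2. **Generalized correlation.** Each edge is weighted by
   *r*<sub>MI</sub> = (1 − e<sup>−2I/d</sup>)<sup>1/2</sup> with *d* = 3,
   where *I* is the mutual information (nats) between the two residues'
   3-D Cα fluctuations, estimated with the Kraskov–Stögbauer–Grassberger
   k-nearest-neighbour estimator (k = 7). Unlike a Pearson coefficient,
   *r*<sub>MI</sub> sees nonlinear coupling and motion along orthogonal
   axes. Means and standard errors are reported over all windows and
   over the windows where the interaction is actually present, and an
   edge is *persistent* when *r*<sub>MI</sub> > 0.3 in at least 15 of 20
   windows.
3. **Optimal paths.** Allosteric routes between a source set (receptor
   residues gripped by the binder) and a target set are shortest paths
   under edge length −ln *r*<sub>MI</sub>, via Floyd–Warshall, pooled
   over windows into an ensemble of unique paths. Noise paths are
   removed by a Jaccard filter: keep a path if it recurs in > 1 window
   or if its edge-set similarity to another path reaches a threshold
   (derived as the largest value at which every path still has a
   neighbour). Filtered paths are classified as *direct* or
   *via-partner* by the regions they traverse.
4. **Binding modes.** Frames are clustered by flat-kernel mean shift
   (bandwidth 2.5 Å) on a 2-D feature space: Cα RMSD of the binder's
   heavy-chain CDR loops vs its light-chain CDR loops, after aligning on
   a receptor reference region.
5. **Contact surface area.** Shrake–Rupley SASA with a 1.7 Å water
   probe on a deterministic 960-point golden spiral; the binder–receptor
   contact area is (S<sub>A</sub> + S<sub>B</sub> − S<sub>complex</sub>)/2,
   reported in nm².

Because real microsecond trajectories are too large to ship, the package
includes a first-class synthetic generator: multi-chain bead systems
whose per-frame displacements follow a prescribed Gaussian correlation
structure, for which mutual information and *r*<sub>MI</sub> have exact
closed forms. Every stage is validated against that analytic ground
truth or a brute-force oracle.

## Worked example

Simulate a small dataset with a strongly, locally coupled binder (four
replicas of 160 frames to keep it quick), then run the pipeline:

```bash
cat > spec.toml <<EOF
mode = "localized_strong"
n_replicas = 4
frames_per_replica = 160
seed = 1
EOF
allosnet simulate spec.toml data
# lower the persistence bar to 6 of the 8 available windows
sed -i 's/\[sets\]/min_windows = 6\n\n[sets]/' data/pipeline.toml
allosnet run data/pipeline.toml run
```

which prints:

```json
{
 "contact_area_nm2": 1.91760328480937,
 "filtered_paths": 47,
 "interface_edge_windows": {"2-37": 8, "4-39": 8, "6-41": 8},
 "n_clusters": 1,
 "n_nodes": 44,
 "n_windows": 8,
 "path_threshold": 0.6666666666666666,
 "persistent_edges": 5,
 "persistent_interface_edges": 3,
 "source_nodes": [2, 4, 6],
 "unique_paths": 47,
 "via_partner_paths": 38
}
```

Reading it: the three planted binder↔receptor couplings are recovered as
persistent interface edges (each correlated in all 8 windows —
`"2-37": 8` means receptor node 2 ↔ binder node 37), their
receptor-side endpoints become the path sources, and 47 unique optimal
routes to the lower-lobe targets are found, 38 of them detouring through
the partner chain — the inter-subunit pathway that a strong localized
binder activates. The binder sits in one binding-mode cluster and buries
≈ 1.9 nm² of interface. Re-running the same mode as `diffuse_weak`
yields zero persistent interface edges and zero paths: a weakly, diffusely
coupled binder does not light up the network.

The same stages are available piecemeal (`allosnet contacts|correlate|
paths|cluster|sasa|report`), and everything is importable as a library
(`allosnet.build_contact_graph`, `allosnet.window_correlations`,
`allosnet.optimal_paths`, …).

## Layout

```
src/allosnet/
  core.py         topology, Kabsch superposition, RMSD, windows, PDB/XYZ I/O
  synthetic.py    Gaussian bead-network generator with analytic ground truth
  contacts.py     per-window heavy-atom contact graphs
  correlation.py  KSG mutual information → generalized correlation, aggregation
  paths.py        Floyd–Warshall path ensembles, Jaccard filter, route classes
  clustering.py   CDR RMSD features, mean-shift binding modes
  surface.py      Shrake–Rupley SASA, contact surface area
  pipeline.py     config, dataset simulation, end-to-end driver
  cli.py          `allosnet` command-line interface
docs/methods.md   model assumptions, parameter choices, limitations
```
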