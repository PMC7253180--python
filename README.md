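# confwire

Analysis toolkit for conformational change and proton-pathway hydration in
CLC-family Cl⁻/H⁺ antiporters — and, more generally, for any membrane
protein study that needs one of its three core analyses:

1. **Water-wire detection in MD trajectories.** Per frame, a hydrogen-bond
   graph is built over all water molecules (geometric criterion: any
   water hydrogen within 2.5 Å of a partner water's oxygen; an O–O ≤ 3.5 Å
   fallback covers hydrogen-free inputs). Waters whose oxygen lies within
   3.5 Å of chosen seed atoms (e.g. the OE1/NE2 amide atoms of the external
   glutamine, residue 148) attach to a virtual seed node; waters with
   oxygen z < −15 Å (membrane center at z = 0) form the intracellular bulk
   set. A breadth-first search returns the pathway with the minimal number
   of water molecules N_w connecting seed to bulk, per frame. Aggregates:
   occurrence fraction f_path, the N_w histogram, route classification by
   marker residues, and voxelized water-occupancy maps (OpenDX export,
   default contour isovalue 0.35).
2. **Conformational comparison of structure pairs.** Cα difference distance
   matrices ΔD = D_A − D_B (independent of any superposition), Kabsch
   rigid-body fits on helix-core subsets (default: helices B, F, G, I —
   residues 35–47, 153–164, 174–190, 215–223 in CLC-ec1 numbering),
   per-residue displacement profiles, and inverted-repeat RMSD tables
   (helices B–I vs J–Q). Side-chain χ-angle extraction with k-means rotamer
   clustering on the (sin, cos) circular embedding supports conditioning
   water maps on rotameric states.
3. **DEER dipolar-signal fitting.** Powder-averaged dipolar kernel
   (Fresnel-integral evaluation, ν_dd = 52.04 MHz·nm³/r³), four-pulse
   model V(t) = e^(−k·|t|)·[1 − λ + λ∫P(r)K(t,r)dr] with a single-Gaussian
   P(r), a five-pulse model whose artifact is an amplitude-scaled,
   time-shifted four-pulse copy, simultaneous 4+5-pulse fitting with shared
   (r₀, σ), and 95% confidence bands on P(r) by the delta method.

A synthetic-data module generates every input class with planted ground
truth (water wires with exact per-frame connectivity records, structure
pairs with known subset displacements, DEER traces from known models), so
the full pipeline is testable without any external downloads.

## Worked example

Generate a 300-frame trajectory with a water wire planted in 50% of frames,
then detect it:

```bash
confwire simulate wire --seed 7 --out demo
confwire waterpath --traj demo.traj.pdb --out demo_scan
```

prints

```
wrote synthetic wire dataset under prefix demo
f_path = 0.4867 over 300 frames
```

`f_path` is the fraction of frames with a continuous hydrogen-bonded
pathway from the seed residue to the bulk slab — here exactly the planted
fraction (146/300 of the generator's Bernoulli draws at p = 0.5). The
per-frame table (`demo_scan.stats.tsv`) lists presence and path length N_w
per frame; `demo_scan.summary.json` holds the N_w histogram, which for this
system is concentrated at the planted chain length of 5 waters.

Fit a synthetic DEER dataset (truth: r₀ = 35 Å, σ = 2 Å):

```bash
confwire simulate deer --seed 3 --out demo_deer
confwire deer-fit --four demo_deer.four.dat --five demo_deer.five.dat --out demo_fit
```

prints

```
wrote synthetic deer dataset under prefix demo_deer
r0 = 35.02 Å, sigma = 1.98 Å, residual RMS = 0.009904
```

with the fitted P(r) and its 95% delta-method bands in `demo_fit.pr.tsv`
and parameter standard errors in `demo_fit.fit.json`.

Measure an inter-residue distance on any PDB structure (e.g. the
glutamate-to-glutamate separation across the proton pathway):

```bash
confwire measure --pdb structure.pdb \
    --sel-a "resid 148 and name OE1 OE2" \
    --sel-b "resid 203 and name OE1 OE2" --mode min
```

## Layout

- `src/confwire/structio.py` — PDB / trajectory I/O, selections, distances
- `src/confwire/hbond_graph.py` — per-frame water H-bond graphs
- `src/confwire/pathway_search.py` — BFS pathways, statistics, occupancy maps
- `src/confwire/conformers.py` — χ angles and rotamer clustering
- `src/confwire/structcompare.py` — DDMs, Kabsch, repeat RMSD
- `src/confwire/deer.py` — dipolar kernel, signal models, joint fitting, bands
- `src/confwire/synthetic_data.py` — generators with planted ground truth
- `src/confwire/cli.py` — the `confwire` command
- `docs/methods.md` — modeling assumptions, parameters, and limitations
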