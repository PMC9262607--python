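# porescan

Trajectory analysis of ssDNA translocation and lesion stalling at the entry
pore of an XPD-type 5′→3′ helicase.

In nucleotide excision repair, the XPD helicase scans single-stranded DNA
and stalls at bulky lesions such as the UV-induced pyrimidine (6−4)
pyrimidone photoproduct (6−4PP), thereby verifying the damage. In MD
simulations of the XPD–ssDNA complex, the difference between scanning and
stalling shows up in a handful of geometric observables around the DNA
entry pore, which is formed by the FeS, Arch and ATPase-lobe-1 domains.
`porescan` computes those observables from trajectories and classifies each
replica's behavior:

* **Pore geometry** — the pore width proxied by the Cα(H135)–Cα(L220)
  distance, the Arch/lobe-1 gap Cα(R380)–Cα(L220), and the shortest
  heavy-atom distance between the R380 side chain and the lobe-1 helix
  (residues 215–221, PKIADLV).
* **Per-nucleotide displacement tracks** — after least-squares (Kabsch)
  superposition of the pore Cα set, the phosphate displacement and
  heavy-atom RMSD of a tracked nucleotide from its reference position,
  with ensemble statistics (mean ± per-frame SD) over an equilibrated
  window detected by a sliding-slope plateau criterion.
* **The one-nucleotide translocation criterion** — a replica is
  backbone-translocated when its equilibrated phosphate displacement
  reaches a configurable fraction (default 0.8) of the ideal B-form
  adjacent phosphate spacing d(P–P) = √((2r sin(Ω/2))² + h²) ≈ 7 Å
  (twist Ω = 36°, rise h = 3.38 Å); a replica whose backbone stays put but
  whose base swings into the pore interior (heavy RMSD ≥ 5 Å, base
  centroid inside the prism spanned by the three domain-anchor centroids)
  is base-translocated; everything else is blocked (base entrapment by the
  FeS pocket or the lobe-1 helix sensors).
* **Interaction networks** — geometric hydrogen-bond detection with
  occupancy accounting ("total HB numbers" are sums of donor–acceptor pair
  occupancies per residue–nucleotide pair), cation-π and methyl-π
  contacts, and van der Waals contact counts.
* **Stage segmentation** — contact-fingerprint changepoints over key
  residue–nucleotide pairs (majority-filtered, with a minimum dwell), plus
  the medoid "most representative structure" of the equilibrated ensemble
  and the backbone-bend metric (cross-loop P–P distance).
* **Synthetic replicas** — a generator that emulates the pore scaffold
  with the named residues and plants known events (7 Å backbone hop, base
  flip, entrapment, ±3.6 Å pore opening), hydrogen-bond occupancies and
  contact epochs under Gaussian coordinate noise, so every pipeline stage
  is testable against analytic ground truth.

## Worked example

Generate one synthetic backbone-translocation replica and run the full
pipeline:

```python
import porescan as ps

top, ref = ps.generate_scaffold()
spec = ps.ScenarioSpec(kind="backbone_translocation", noise_sigma=0.5, seed=1)
traj, truth = ps.generate_trajectory(spec)
report = ps.analyze_replica(traj, ref, [1], with_representative=False)
print(report.behavior.label, report.window)
print(report.tracks["1"]["p_displacement"])
```

prints

```
backbone_translocation (1510.0, 1990.0)
{'mean': 7.137..., 'sd': 0.496..., 'window': [1510.0, 1990.0], 'n_frames': 49}
```

The tracked nucleotide's equilibrated phosphate displacement (7.1 ± 0.5 Å)
reaches the ~7 Å B-form spacing, so the replica is labelled a one-nucleotide
backbone translocation; the window (1510–1990 ns) is the detected
equilibrated plateau. A panel of replicas aggregates into a population
table:

```python
reports = []
for s in ps.default_fixture_specs(n_per_class=3, noise_sigma=0.5):
    t, _ = ps.generate_trajectory(s)
    reports.append(ps.analyze_replica(t, ref, [1], with_representative=False))
print(ps.replica_summary(reports).to_string(index=False))
```

```
                 label  count  percent
backbone_translocation      3       33
    base_translocation      3       33
               blocked      3       33
```

The same pipeline runs from the shell: `porescan synth --preset default30
--out fixtures/` writes 30 replicas with ground truth, `porescan analyze
--config run.yaml` writes a JSON report plus per-series CSVs for one
replica, and `porescan population 'out/*.report.json'` prints the
population table.

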