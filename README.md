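# chromostoch

Quantitative analysis of single-cell chromosome organization, with a
synthetic-data module so every stage can be exercised end to end without
external data.

The package covers five analysis stages and their simulated inputs:

| Module | What it does |
| --- | --- |
| `chromostoch.synthetic_data` | Generates every pipeline input with known ground truth: 3D nucleus stacks with Gaussian-blob loci, paired-locus cell populations, freely jointed polymer chains, clustered 2D SMLM localization fields, alternating ChIP domain tracks, and biased distance-decay contact matrices. |
| `chromostoch.simfoci` | Nucleus segmentation (low-pass + averaged per-plane thresholds), maximum-entropy foci thresholding, 3D connected-component foci detection with sub-voxel centers, closest-foci distances, p(r), radius of gyration and D_max. |
| `chromostoch.diststats` | Gaussian fits to distance distributions, absolute contact probability below a 120-nm cutoff (Φ form with bootstrap SEM), dispersion-distance and power-law/exponential fits, chromatin scaling exponents, resolvable-foci pairing model. |
| `chromostoch.storm` | Coordinate-based colocalization (CBC) of two-channel localizations, Voronoi-tessellation compartment segmentation with equivalent diameters on a 5-nm grid, density-normalized size histograms, Pearson/Manders rendered-image controls. |
| `chromostoch.chromdomains` | Peak tracks → continuous signal → log-thresholded domains (>2 bp, sub-1-kb gaps fused) → predicted physical sizes via the empirical power law → clustering percentage vs imaged compartments. |
| `chromostoch.hicmat` | Dense text contact matrices with BED3 bin tables: low-coverage bin filtering, ICE normalization (10% change / 10 iteration stopping rule, mean-1 rescale), distance-decay profiles with random baselines, pairwise extraction, log2 ratio matrices. |
| `chromostoch.cli` | `chromostoch` command-line entry point and demo pipelines. |

## Tests

```sh
python -m pytest -q tests/
```

The suite includes unit tests per module, property-based invariant tests
(hypothesis), and `tests/test_acceptance.py` with the acceptance criteria
(resolvable-foci bound, ICE mean-1 contract, random-coil exponent
recovery, and the oracle-equivalence property suites).

## Command line

```sh
chromostoch demo --seed 1 --out demo_out            # both demo pipelines
chromostoch simulate-hic --seed 0 --n-bins 200 --out hic.txt
chromostoch hic-ice --matrix hic.txt --bins hic.bins.bed --out iced.txt
chromostoch simulate-storm --seed 1 --mode co-occurring --out locs.csv
chromostoch storm-voronoi --locs locs.csv --out compartments.csv
chromostoch storm-cbc --locs locs.csv --out ca.csv
chromostoch simulate-chip --seed 2 --out peaks.bed
chromostoch domains-call --bed peaks.bed --out domains.csv
chromostoch simulate-images --seed 3 --out imgs/
chromostoch detect-foci --dapi imgs/dapi.tif --ch1 imgs/ch1.tif --out foci.csv
```

Every subcommand is deterministic given `--seed`; pipeline runs write the
resolved configuration (`config.json`) and a provenance block next to
their outputs.

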