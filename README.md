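# fragrank

**In-silico fragmentation and candidate ranking for tandem mass spectrometry.**

Identifying a small molecule from a tandem MS (MS/MS) spectrum is the main
bottleneck of metabolomics: spectral libraries of measured reference
compounds cover only a sliver of chemical space, while structure databases
(KEGG, PubChem, …) describe orders of magnitude more compounds — but
without spectra. `fragrank` bridges the gap for the practitioner who has a
peak list and a precursor mass: it retrieves every candidate structure of
matching exact mass from a local library, fragments each candidate *in
silico* by combinatorial bond disconnection, matches the hypothetical
fragments to the measured peaks, and ranks the candidates by how well —
and how plausibly — they explain the spectrum.

## The method

For each candidate, a fragmentation tree is enumerated breadth-first: one
cleavage event (a single acyclic bond, or a pair of ring bonds removed
simultaneously) per tree level, up to a maximum depth (default 2).
Hydrogens travel with their heavy atom. Fragments lighter than the
smallest query peak are never generated, and duplicates are eliminated (by
molecular formula by default, with atom-subset and graph-isomorphism modes
available); among duplicates the fragment requiring the lowest bond
dissociation enthalpy (BDE) is kept. A small table of neutral-loss rules
(H₂O, HCN, NH₃, CH₂O, HCOOH) covers rearrangements that pure bond
disconnection cannot reach, e.g. water loss from a hydroxyl group plus a
remote C–H hydrogen.

A fragment of neutral mass *m* explains a measured peak at *m/z* if
|*m/z* − (*m* ± *m*_H⁺)| ≤ mzabs + mzppm·10⁻⁶·(*m* ± *m*_H⁺), the proton
(1.007 Da) added in positive and removed in negative mode. Candidate *i*
is then scored

```
S_i = w_i / max(w) − e_i / (2·max(e)),     w_i = Σ_peaks int^0.6 · mz^3
```

where *w_i* sums over the peaks candidate *i* explains (heavy, intense
peaks count more) and *e_i* is the mean dissociation enthalpy of the bonds
cleaved to produce its explaining fragments — implausible, strong-bond
explanations are penalized. S lies in [−0.5, 1].

Because large libraries return many near-identical structures, ranks are
reported pessimistically: the *worst-case rank* counts the whole tied
block (a top score shared by 10 candidates means rank 10 for each), and
the *cluster rank* first collapses tied candidates with fingerprint
Tanimoto similarity ≥ 0.95 (stereoisomers in particular) into single
compound clusters.

## Worked example

Simulate a spectrum of phenol, score it against a decoy library, and rank:

```sh
fragrank simulate --molecule phenol --seed 3 --decoys 8 --out sim/
fragrank run --peaks sim/spectrum.txt --library sim/library.sdf \
             --neutral-mass 94.0419 --mzabs 0.002 --mzppm 10 --out out/
fragrank evaluate out/results.csv --truth phenol
```

which prints

```
wrote 6 peaks and 9 library records to sim
9 candidates scored; results in out
{
  "worst_case_rank": 1,
  "cluster_rank": 1,
  "ppv": 0.35294117647058826,
  "rank_summary": {
    "mean": 5.222222222222222,
    "median": 5.0,
    "q75": 7.0,
    "std": 2.5873624493766707
  }
}
```

The true structure explains all six simulated peaks through low-enthalpy
cleavages and tops the table; the decoys explain fewer peaks, or only
through implausible bond breaks. `out/results.csv` lists every candidate
with its score, weighted peak count, mean BDE, and both rank conventions;
`out/matches.csv` lists each explained peak with the fragment's formula,
SMILES, mass error and broken-bond enthalpy.

The same machinery is available as a library:

```python
from fragrank import *

naringenin = toy_molecule_set()[0]
spectrum  = simulate_spectrum(naringenin, SimulationConfig(seed=0))
library   = make_decoy_library(naringenin, n=100, seed=0)
scored    = score_spectrum([r.molecule for r in library], spectrum,
                           FragmenterConfig(max_depth=2),
                           MatchParams(mzabs=0.001, mzppm=10),
                           rules=default_rules())
ranked    = rank_candidates(scored, [fingerprint(r.molecule) for r in library])
```

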