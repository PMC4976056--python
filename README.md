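# mvcpair

Pair-matching of bilateral skeletal elements from 3D surface meshes by
**mesh-to-mesh value comparison (MVC)**.

## The problem

When skeletal remains from several individuals are commingled — mass
graves, disasters, disturbed archaeological contexts — a first step of
individualization is re-associating left and right antimeres (e.g. the
left and right humerus of one person). Classical approaches (visual
matching, osteometric comparison, landmark-based geometric morphometrics)
either depend on observer experience, use only a handful of measurements,
or require reproducible anatomical landmarking. MVC instead compares the
*entire* digital 3D surface of two bones: mirror one side, rigidly
register each left–right candidate pair, and summarise the residual
surface difference as a single value in millimetres. Low values mean
similar bones; the lower the value, the better the match. Because paired
elements of one individual differ only by bilateral asymmetry (tenths of
a millimetre) while different individuals differ by millimetres, the
matrix of all left × right values carries a strong pairing signal without
any landmarking.

## Method

For a left mesh `L` and a mirrored right mesh `R'`:

1. **Rough alignment** — multi-start point-to-point ICP on a fixed random
   1 % vertex sample, approximate nearest neighbours, up to 100
   iterations. The 20 starting orientations come from principal-axis
   alignment, its four proper axis flips, and quasi-uniform random
   rotations.
2. **Fine alignment** — point-to-plane ICP on 100 % of the vertices,
   exact nearest neighbours, correspondences rejected when surface
   normals disagree by more than 45°, up to 100 iterations. With the
   default estimated overlap of 100 % no residual trimming is applied.
3. **Mesh-to-mesh value** — under the final transform `T`,

   `MVC(L, R') = sqrt[ (Σᵢ d²(T·lᵢ, R') + Σⱼ d²(rⱼ, T·L)) / (n_L + n_R) ]`

   the symmetric RMS nearest-neighbour distance over all vertices of both
   meshes, in mm.
4. **Matching rule** — a pair (L, R) is declared iff each bone is the
   other's single lowest-value candidate in the comparison matrix
   (*mutual best*). Every bone's three lowest candidates are retained for
   audit. Bones in no declared pair are declared singletons.
5. **Evaluation** — against known pairings, counted per bone: a bone in a
   correct pair is a true positive, a bone in a wrong pair a false
   positive, a truly paired bone left single a false negative, a true
   singleton left single a true negative; sensitivity = TP/(TP+FN),
   specificity = TN/(TN+FP).

A mean + 2·SD threshold fitted to the true-pair values is computed as a
diagnostic (`threshold_analysis`), not as a declaration rule: whenever the
true-pair and non-pair value distributions overlap, a single cutoff
admits impostors that the two-sided matrix rule rejects.

Because no open collection of paired bone scans can ship with the
package, `mvcpair.synthetic` generates populations of long-bone-like
meshes with controlled between-individual shape variation, within-pair
bilateral asymmetry (a smooth displacement field of given RMS magnitude),
per-vertex scan noise, optional singletons, and random initial pose.

## Worked example

```sh
mvcpair simulate --out bones --pairs 3 --left-singletons 0 --right-singletons 1 --seed 7
mvcpair compare bones bones --out matrix.csv --seed 7
mvcpair match matrix.csv --out report.json
mvcpair evaluate report.json bones/truth.csv
```

The comparison matrix (`matrix.csv`, values in mm):

```
left_id,ind000_R,ind001_R,ind002_R,sing000_R
ind000_L,0.311906,2.29193,2.6383,3.025
ind001_L,2.41056,0.384561,2.98995,4.69077
ind002_L,2.42417,2.71271,0.341811,4.22754
```

Each true pair sits on the diagonal at 0.31–0.38 mm — the planted 0.3 mm
bilateral asymmetry plus discretisation — while non-pairs are 2.3–4.7 mm.
All three diagonal cells are mutual row/column minima, so `match` declares
exactly the three true pairs and leaves the unpaired right bone single;
`evaluate` prints:

```
| Quantity | Count |
| --- | --- |
| True positives | 6 |
| False negatives | 0 |
| False positives | 0 |
| True negatives | 1 |
| Sensitivity | 100 % |
| Specificity | 100 % |
```

The same pipeline is available as library calls: `generate_population` →
`compare_all` → `mutual_match` → `score`.

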