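# ntckit built-in dinucleotide conformer-class catalog (stand-in, v1).
#
# Torsions in degrees, (-180, 180].  AA00/BB00 are the package's calibrated
# fiber-like A/B-form step torsions (the same values drive the synthetic
# duplex builder, so builder output at zero noise re-assigns exactly).  The
# remaining classes are literature-informed offsets chosen to span the
# qualitative phenomena (B-II epsilon/zeta crankshaft, unusual alpha/gamma
# combinations with low or high beta, A/B mixed steps); they do not claim to
# reproduce the external golden-set centroids.  cana groups classes into the
# coarse structural-alphabet codes.  tol is the per-torsion restraint
# tolerance (degrees).
name	cana	delta1	epsilon1	zeta1	alpha2	beta2	gamma2	delta2	chi1	chi2	tol
AA00	AAA	83.0	-143.3	-80.0	-59.9	153.3	55.1	83.0	-162.2	-162.2	25.0
AA08	AAA	83.0	-98.0	-165.0	-65.0	160.0	52.0	83.0	-155.0	-155.0	25.0
AA06	AAw	83.0	-143.3	-80.0	180.0	153.3	180.0	83.0	-162.2	-162.2	25.0
AA10	AAw	83.0	-143.3	-80.0	-60.0	80.0	55.0	83.0	-162.2	-162.2	25.0
AA11	AAw	83.0	-143.3	-80.0	55.0	-155.0	-70.0	83.0	-162.2	-162.2	25.0
AA12	AAw	83.0	-130.0	-65.0	-140.0	120.0	175.0	83.0	-120.0	-120.0	25.0
BB00	BBB	135.0	-145.7	-144.6	-38.7	141.3	39.5	135.0	-149.2	-149.2	25.0
BB01	BBB	135.0	-170.0	-100.0	-30.0	120.0	30.0	135.0	-110.0	-110.0	25.0
BB07	BB2	135.0	-95.0	175.0	-38.7	141.3	39.5	135.0	-110.0	-110.0	25.0
BA05	B-A	135.0	-145.0	-110.0	-55.0	160.0	50.0	83.0	-130.0	-155.0	25.0
AB01	A-B	83.0	-145.0	-80.0	-45.0	145.0	42.0	135.0	-160.0	-120.0	25.0
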