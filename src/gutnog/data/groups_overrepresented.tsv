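nog_ids	function	category	catalog_pct	gut_pct	nongut_pct
bactNOG57079	5-Aminoimidazole-4-Carboxamide ribonucleotide transformylase	[F] Nucleotide transport and metabolism	1.4	100.0	26.1
bactNOG33416	Transcriptional regulator protein-like protein	[K] Transcription	0.4	73.9	0.0
bactNOG14419,bactNOG78827	Site-Specific recombinase	NA	NA	87.0	17.4
bactNOG20561	Sulfuric ester hydrolase	[M] Cell wall/membrane/envelope biogenesis	11.1	82.6	13.0
bactNOG61174	Replication initiator protein	[S] Function unknown	0.2	69.6	0.0
bactNOG43319,bactNOG30533,bactNOG35352	Adenylate cyclase	NA	NA	78.3	13.0
bactNOG14637	Adenylosuccinate protein	[F] Nucleotide transport and metabolism	2.6	69.6	4.3
bactNOG13499	Selenate reductase subunit YgfM; with YgfK and YgfN forms a selenate reductase, which seems to catalyze the reduction of selenate to selenite; YgfM contains a FAD domain-containing protein	[C] Energy production and conversion	3.4	69.6	4.3
bactNOG78875	GB:X04470, GB:X04503, GB:X04502, SP:P03973, PID:28639, PID:338233, PID:36491, and PID:758101; identified by sequence similarity protein	[K] Transcription	0.3	65.2	0.0
bactNOG03861	Elongation factor G	[J] Translation, ribosomal structure and biogenesis	18.7	82.6	17.4
bactNOG10082	SAM dependent methyltransferase	[R] General function prediction only	7.2	82.6	17.4
bactNOG29973	Deoxycytidylate deaminase	[F] Nucleotide transport and metabolism	4.6	73.9	8.7
bactNOG20957,bactNOG28451,bactNOG18161,bactNOG37597	Specifically catalyzes the dephosphorylation of 2- phosphoglycolate. Is involved in the dissimilation of the intracellular 2-phosphoglycolate formed during the DNA repair of 3'-phosphoglycolate ends, a major class of DNA lesions induced by oxidative stress (By similarity) protein	NA	NA	95.7	34.8
bactNOG04076	Zinc phosphodiesterase, which displays some tRNA 3'- processing endonuclease activity. involved in tRNA maturation, by removing a 3'-trailer from precursor tRNA (By similarity)	[R] General function prediction only	5.1	65.2	4.3
bactNOG05123,bactNOG07417	2-Isopropylmalate synthase	NA	NA	91.3	30.4
bactNOG51505,bactNOG44758	Addiction module toxin, RelE/StbE family protein	NA	NA	73.9	13.0
bactNOG45170	Cdp-Diacylglycerol--Glycerol-3-Phosphate 3 protein	[I] Lipid transport and metabolism	5.8	73.9	13.0
bactNOG30240	Glyoxalase/Bleomycin resistance protein/Dioxygenase	[E] Amino acid transport and metabolism	2.9	69.6	8.7
bactNOG00016	Phosphoserine aminotransferase; catalyzes the formation of 3-phosphonooxypyruvate and glutamate from O-phospho-L-serine and 2-oxoglutarate; required both in major phosphorylated pathway of serine biosynthesis and in the biosynthesis of pyridoxine	[E] Amino acid transport and metabolism	41.7	95.7	39.1
bactNOG40424	Glycoside hydrolase, family 25	[M] Cell wall/membrane/envelope biogenesis	1.5	60.9	4.3
bactNOG02826	4-Alpha-Glucanotransferase	[G] Carbohydrate transport and metabolism	44.2	91.3	34.8
bactNOG03506	Aminopeptidase 2; catalyzes the removal of amino acids from the N termini of peptides	[E] Amino acid transport and metabolism	10.9	87.0	30.4
bactNOG15648,bactNOG74792	Aconitate hydratase	[C] Energy production and conversion	NA	78.3	21.7
bactNOG65104	Phosphoribosylpyrophosphate synthetase; Catalyzes the formation of PRPP from ATP and ribose 5-phosphate	[F] Nucleotide transport and metabolism	1.8	78.3	21.7
bactNOG20523	Sugar phosphatase; YidA; catalyzes the dephosphorylation of erythrose 4-phosphate (preferred substrate), mannose 1-phosphate and p-nitrophenyl phosphate; hydrolyzes the alpha-D-glucose-1-phosphate but not the beta form; member of the haloacid dehalogenase-like hydrolases superfamily and Cof family of proteins	[R] General function prediction only	10.2	78.3	21.7
bactNOG30560,bactNOG37582	Removes the formyl group from the N-terminal Met of newly synthesized proteins. Requires at least a dipeptide for an efficient rate of reaction. N-terminal L-methionine is a prerequisite for activity but the enzyme has broad specificity at other positions (By similarity)	NA	NA	69.6	13.0
bactNOG83597	Subunit C	[C] Energy production and conversion	0.4	65.2	8.7
bactNOG31052,bactNOG35249,bactNOG35454,bactNOG05302	Had-Superfamily hydrolase, subfamily IA, variant 3	NA	NA	87.0	34.8
bactNOG07070,bactNOG11507,bactNOG08200,bactNOG10025,bactNOG13178,bactNOG26309	Protein involved in unidirectional conjugation	NA	NA	87.0	34.8
bactNOG22665,bactNOG08175	Pyridoxal kinase	[H] Coenzyme transport and metabolism	NA	87.0	34.8
bactNOG74867,bactNOG16222	Sugar Hydrogen symporter protein	NA	NA	87.0	34.8
bactNOG82609	Oxaloacetate decarboxylase	[C] Energy production and conversion	21.0	78.3	26.1
bactNOG62080	Ribosomal protein S3	[J] Translation, ribosomal structure and biogenesis	0.4	60.9	8.7
bactNOG17864,bactNOG34439	RNA methyltransferase	[J] Translation, ribosomal structure and biogenesis	NA	60.9	8.7
bactNOG14801	Hydro-Lyase, Fe-S type, tartrate/fumarate subfamily, beta	[C] Energy production and conversion	8.6	91.3	39.1
bactNOG02215	Potassium transporter peripheral membrane component; involved in potassium uptake; found to be peripherally associated with the inner membrane in Escherichia coli; contains an NAD-binding domain protein	[P] Inorganic ion transport and metabolism	32.2	91.3	39.1
bactNOG45092	50S ribosomal protein L30; L30 binds domain II of the 23S rRNA and the 5S rRNA	[J] Translation, ribosomal structure and biogenesis	24.4	56.5	4.3
bactNOG70972	Sortase B	[S] Function unknown	1.7	56.5	4.3
bactNOG53104	Histidine Phosphotransfer domain-containing protein	[T] Signal transduction mechanisms	0.3	52.2	0.0
bactNOG99320	Ribosomal protein L34	[J] Translation, ribosomal structure and biogenesis	0.3	52.2	0.0
bactNOG01580	Decarboxylase, beta	[C] Energy production and conversion	15.4	82.6	30.4
bactNOG24561,bactNOG09355	L-Fucose isomerase	[G] Carbohydrate transport and metabolism	NA	73.9	21.7
bactNOG69266,bactNOG44258	Protein involved in conjugation with cellular fusion	NA	NA	73.9	21.7
bactNOG30123,bactNOG62262,bactNOG63699,bactNOG39777	Transcriptional regulator, DeoR family protein	NA	NA	73.9	21.7
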