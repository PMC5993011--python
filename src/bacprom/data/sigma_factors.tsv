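domain	name	description	operons
sigma54	SigL	RNA polymerase sigma-54 (Sigma L)	6
sigma70	SigA	RNA polymerase major sigma-43 (Sigma A). Essential gene.	358
sigma70	SigB	RNA Polymerase sigma-37 (Sigma-B). General stress factor sigma.	67
sigma70	SigD	RNA polymerase sigma-28 (Sigma D). Autolytic enzymes; defect in flagellar synthesis.	30
sigma70	SigE	RNA polymerase sporulation-specific sigma-29. Processed by SpoIIGA after Tyr-27.	83
sigma70	SigF	Synthesized shortly after the onset of sporulation but do not become active until after polar division.	30
sigma70	SigG	Control of transcription in the forespore at late stages of sporulation.	61
sigma70	SigH	RNA polymerase sigma-30. Non-essential sigma factor involved in expression of vegetative and early stationary-phase genes.	24
sigma70	SigI	Temperature-sensitive growth in a null mutant; transcription induced by heat shock in rich medium but not in minimal medium; reduced amount of GsiB protein in a sigI mutant under heat shock conditions.	1
sigma70	SigK	Formed by a site-specific recombination event that joins the previously separated spoIVCB and spoIIIC genes into a single cistron.	59
sigma70	SigM	Essential for growth and survival in high concentrations of salt; expression maximal during exponential growth and increased in high concentrations of salt; activity negatively regulated by YhdL and YhdK.	7
sigma70	SigW	ECF-type sigma factor that mediates the transcriptional response to cell wall stress.	34
sigma70	SigX	RNA polymerase SigX.	15
sigma70	SigY	RNA polymerase ECF(extracytoplasmic function)-type sigma factor	2
sigma70	YlaC	RNA polymerase ECF(extracytoplasmic function)-type sigma factor	1
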