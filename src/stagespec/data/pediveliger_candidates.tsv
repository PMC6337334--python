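gene_id	protein_id	product_name	functional_group	localization
CGI_10014580	EKC18206	Hypothetical protein CGI_10014580	Hypothetical protein	Mit 0.58
CGI_10010208	EKC18972	Hypothetical protein CGI_10010208	Hypothetical protein	Ext 1
CGI_10004853	EKC21005	Hypothetical protein CGI_10004853	Hypothetical protein	Ext 0.42
CGI_10002578	EKC22248	Hypothetical protein CGI_10002578	Hypothetical protein	Ext 0.89
CGI_10001746	EKC22673	Hypothetical protein CGI_10001746	Hypothetical protein	Ext 0.90
CGI_10013335	EKC23310	Hypothetical protein CGI_10013335	Hypothetical protein	Nuc 0.50
CGI_10013386	EKC24388	Hypothetical protein CGI_10013386	Hypothetical protein	Ext 0.41
CGI_10005578	EKC25384	Hypothetical protein CGI_10005578	Hypothetical protein	Ext 0.43
CGI_10013385	EKC24387	Hypothetical protein CGI_10013385	Hypothetical protein	Ext 0.60
CGI_10003237	EKC27225	Hypothetical protein CGI_10003237	Hypothetical protein	Ext 0.99
CGI_10025142	EKC28625	Hypothetical protein CGI_10025142	Hypothetical protein	Ext 0.91
CGI_10009961	EKC31321	Hypothetical protein CGI_10009961	Hypothetical protein	Ext 0.99
CGI_10025191	EKC32101	Hypothetical protein CGI_10025191	Hypothetical protein	Cyt 0.38
CGI_10012470	EKC33059	Hypothetical protein CGI_10012470	Hypothetical protein	Ext 0.99
CGI_10016093	EKC35263	Hypothetical protein CGI_10016093	Hypothetical protein	Ext 0.52
CGI_10016094	EKC35264	Hypothetical protein CGI_10016094	Hypothetical protein	Ext 0.52
CGI_10027526	EKC35968	Hypothetical protein CGI_10027526	Hypothetical protein	ER 0.40
CGI_10026725	EKC38958	Hypothetical protein CGI_10026725	Hypothetical protein	Ext 0.62
CGI_10022908	EKC41146	Hypothetical protein CGI_10022908	Hypothetical protein	ER 0.25
CGI_10008429	EKC41249	Hypothetical protein CGI_10008429	Hypothetical protein	Ext 0.90
CGI_10013282	EKC42653	Hypothetical protein CGI_10013282	Hypothetical protein	Nuc 0.59
CGI_10009044	EKC19270	Putative tyrosinase-like protein tyr 1	Enzyme	Mem 0.82
CGI_10014286	EKC25254	Putative tyrosinase-like protein tyr-3	Enzyme	Mem 0.99
CGI_10006802	EKC29117	Tyrosinase-like protein 1	Enzyme	Ext 0.64
CGI_10016593	EKC32997	Peroxidase-like protein	Enzyme	Ext 0.49
CGI_10010889	EKC32754	Carbonic anhydrase 2	Enzyme	Cyt 0.41
CGI_10011324	EKC18733	Carbonic anhydrase 7	Enzyme	Ext 0.65
CGI_10003099	EKC28981	Cell surface hyaluronidase-like	Enzyme	Plast 0.39
CGI_10003100	EKC28982	Cell migration-inducing and hyaluronan-binding protein-like	Enzyme	Cyt 0.29
CGI_10007190	EKC19955	Metalloendopeptidase	Enzyme	Ext 0.39
CGI_10007191	EKC19956	Metalloendopeptidase	Enzyme	Ext 0.51
CGI_10020760	EKC31184	Zinc metalloproteinase nas-15	Enzyme	Ext 0.70
CGI_10010154	EKC18991	Serine protease inhibitor dipetalogastin-like	Protease inhibitor	Ext 0.55
CGI_10010155	EKC18992	Serine protease inhibitor dipetalogastin-like	Protease inhibitor	Ext 1
CGI_10005627	EKC20685	Hemicentin-1	Structural protein	Ext 0.72
CGI_10010553	EKC18864	IgGFc-binding protein (zonadhesin-like)	Structural protein	Ext 0.64
CGI_10010554	EKC18865	IgGFc-binding protein (zonadhesin-like)	Structural protein	Ext 0.72
CGI_10010555	EKC18866	IgGFc-binding protein (zonadhesin-like)	Structural protein	Ext 0.93
CGI_10010556	EKC18867	IgGFc-binding protein (zonadhesin-like)	Structural protein	Ext 0.60
CGI_10010557	EKC18868	IgGFc-binding protein (zonadhesin-like)	Structural protein	Ext 0.91
CGI_10023170	EKC34632	IgGFc-binding protein	Structural protein	Ext 0.52
CGI_10010465	EKC34579	Tenascin-X	Structural protein	Ext 0.80
CGI_10000981	EKC39076	Tenascin-R	Structural protein	Ext 0.84
CGI_10025295	EKC40994	Multiple EGF-like domains 10	Structural protein	Ext 0.42
CGI_10013281	EKC42652	Tenascin-R	Structural protein	Ext 0.99
CGI_10010827	EKC18813	Collagen-like protein 7	Structural protein	Ext 0.89
CGI_10010374	EKC27350	Collagen-like protein 7	Structural protein	Mem 0.56
CGI_10010375	EKC27351	Collagen-like protein 7	Structural protein	Mem 0.72
CGI_10011175	EKC27706	Collagen alpha-5(VI) chain	Structural protein	Ext 0.55
CGI_10010615	EKC18891	Aggrecan core protein	Calcification-related protein and calcium-binding protein	Ext 0.79
CGI_10006917	EKC42164	Asialoglycoprotein receptor 2	Calcification-related protein and calcium-binding protein	Ext 0.99
CGI_10006919	EKC42165	Perlucin-like protein	Calcification-related protein and calcium-binding protein	Ext 0.95
CGI_10006920	EKC42166	C-type mannose receptor 2	Calcification-related protein and calcium-binding protein	Ext 0.90
CGI_10006921	EKC42167	Perlucin-like protein	Calcification-related protein and calcium-binding protein	Ext 0.99
CGI_10006922	EKC42168	Perlucin-like protein	Calcification-related protein and calcium-binding protein	Ext 0.99
CGI_10008331	EKC19532	Protocadherin Fat 4-like	Calcification-related protein and calcium-binding protein	Lys 0.36
CGI_10018326	EKC34251	Protocadherin Fat 4	Calcification-related protein and calcium-binding protein	Cyt 0.72
CGI_10022907	EKC41145	Protocadherin Fat 4-like	Calcification-related protein and calcium-binding protein	Cyt 0.44
CGI_10006247	EKC20329	Putative calmodulin	Calcification-related protein and calcium-binding protein	Cyt 0.48
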