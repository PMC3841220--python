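mapping_id	cancer_type	normal_tissue	normal_cell_type
Breast	Breast cancer	breast	glandular cells
Carcinoid	Carcinoid	pancreas	islets of Langerhans
Cervical-A	Cervical cancer	cervix, uterine	glandular cells
Cervical-B	Cervical cancer	cervix, uterine	squamous epithelial cells
Colorectal-A	Colorectal cancer	colon	glandular cells
Colorectal-B	Colorectal cancer	rectum	glandular cells
Endometrial-A	Endometrial cancer	uterus, pre-menopause	glandular cells
Endometrial-B	Endometrial cancer	uterus, post-menopause	glandular cells
Glioma	Glioma	cerebral cortex	glial cells
Head & neck-A	Head and neck cancer	oral mucosa	squamous epithelial cells
Head & neck-B	Head and neck cancer	salivary gland	glandular cells
Cholangio	Cholangiocarcinoma	liver	bile duct cells
Hepato	Hepatocellular carcinoma	liver	hepatocytes
Lung-A	Lung cancer	bronchus	respiratory epithelial cells
Lung-B	Lung cancer	lung	pneumocytes
Lymphoma-A	Lymphoma	lymph node	germinal center cells
Lymphoma-B	Lymphoma	lymph node	non-germinal center cells
Melanoma	Melanoma	skin	melanocytes
Pancreatic	Pancreatic cancer	pancreas	exocrine glandular cells
Prostate	Prostate cancer	prostate	glandular cells
Renal	Renal cancer	kidney	cells in tubules
Skin	Skin cancer	skin	keratinocytes
Stomach-A	Stomach cancer	stomach, lower	glandular cells
Stomach-B	Stomach cancer	stomach, upper	glandular cells
Testis	Testis cancer	testis	cells in seminiferus ducts
Thyroid	Thyroid cancer	thyroid gland	glandular cells
Urothelial	Urothelial cancer	urinary bladder	urothelial cells
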