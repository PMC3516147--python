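/root/pkg/src/dbmtestevaluate.pydata_model.pyweighting.pyansari_bradley.py__init__.pysimulate.pydbm.py��c��*���fVI��         �   ����>����<ZfVI��         �   �����`yV}�fVI��         �   y������q:fVI��         cli.py��ͤ���DE)fVI��         io.py������]5�JfVI��         �   ���s�\!�B�\fVI��         �   �����E�U�)�fVI��         �   ����<�a���?fVI��                                         �4d:7*�4d:7*����������� �   @�������	   
   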