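/root/pkg/teststest_evaluate.pytest_simulate.pytest_ansari_bradley.pytest_dbm.pyconftest.pytest_data_model.pytest_io.pytest_acceptance.pytest_cli.pytest_weighting.py   �   �����)Y�
u�fVI��         �   �����[�w��fVI��         �   ����e#c��f\�fVI��                                         �   E����_�5&<zfVI��         �   ����`�lD�AIfVI��         �   �����i��J�>9fVI��         �   �����}������fVI��         �   �����:�ǳx�
fVI��         �   W�����4_ݼAfVI��         �   '���YW���6d�fVI��         FP?!S"s�yDFP?!S"s�yD��������� �   ��������
      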